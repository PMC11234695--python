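"""QTL correlations, pseudo-R2, core haplotype, LD and interval overlap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coregqtl.coreg import (core_haplotype, ld_r2, pseudo_r2, qtl_correlation,
                            variant_density_percentile, variant_peak_overlap)
from coregqtl.datatypes import (GenotypeMatrix, Peak, PeakSet, QtlSummary,
                                VariantRecord)


def make_summary(rng, n=50, name="q", beta=None, p=None, flip_alleles=False):
    beta = rng.normal(size=n) if beta is None else np.asarray(beta, dtype=float)
    se = np.abs(rng.uniform(0.05, 0.2, n))
    p = 2 * stats.norm.sf(np.abs(beta / se)) if p is None else np.asarray(p)
    p = np.clip(p, 1e-300, 1.0)
    ref, alt = ("C", "A") if flip_alleles else ("A", "C")
    return QtlSummary(pd.DataFrame({
        "id": [f"v{i}" for i in range(n)],
        "chrom": "22", "pos": np.arange(1, n + 1) * 100,
        "ref": ref, "alt": alt, "maf": 0.3, "n": 100,
        "beta": beta, "se": se, "p": p, "status": "ok",
    }), name=name)


class TestQtlCorrelation:
    def test_self_correlation_is_one(self, rng):
        a = make_summary(rng)
        r = qtl_correlation(a, a)
        for field in ("pearson_beta", "spearman_beta", "pearson_logp",
                      "spearman_logp"):
            assert getattr(r, field) == pytest.approx(1.0)

    def test_negated_betas(self, rng):
        a = make_summary(rng, name="a")
        t = a.table.copy()
        t["beta"] = -t["beta"]
        b = QtlSummary(t, name="b")
        r = qtl_correlation(a, b)
        assert r.pearson_beta == pytest.approx(-1.0)
        assert r.pearson_logp == pytest.approx(1.0)

    def test_allele_flip_harmonized(self, rng):
        a = make_summary(rng, name="a")
        t = a.table.copy()
        t["ref"], t["alt"] = t["alt"], t["ref"]
        t["beta"] = -t["beta"]  # same signal reported on the other allele
        b = QtlSummary(t, name="b")
        r = qtl_correlation(a, b)
        assert r.pearson_beta == pytest.approx(1.0)

    def test_matches_rank_then_correlate_oracle(self, rng):
        a = make_summary(rng, name="a")
        b = make_summary(rng, name="b")
        r = qtl_correlation(a, b)
        x, y = a.table["beta"].to_numpy(), b.table["beta"].to_numpy()
        assert r.pearson_beta == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert r.spearman_beta == pytest.approx(np.corrcoef(rx, ry)[0, 1],
                                                abs=1e-12)

    def test_too_few_shared_variants(self, rng):
        a = make_summary(rng, n=2)
        with pytest.raises(ValueError, match="2"):
            qtl_correlation(a, a)


class TestPseudoR2:
    def test_identical_vectors_give_one(self, rng):
        a = make_summary(rng, name="a")
        b = QtlSummary(a.table.assign(), name="b")
        c = QtlSummary(a.table.assign(), name="c")
        r = pseudo_r2([a, b, c])
        assert r.pseudo_r2_beta == pytest.approx(1.0)
        assert r.pseudo_r2_logp == pytest.approx(1.0)

    def test_orthogonal_standardized_vectors_give_third(self, rng):
        n = 30
        M = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # exactly uncorrelated columns
        summaries = [make_summary(rng, n=n, name=nm, beta=Q[:, k])
                     for k, nm in enumerate("abc")]
        r = pseudo_r2(summaries, mode="correlation")
        assert r.pseudo_r2_beta == pytest.approx(1 / 3, abs=1e-9)

    def test_matches_eigen_oracle(self, rng):
        for mode in ("correlation", "covariance"):
            summaries = [make_summary(rng, name=nm) for nm in "abc"]
            r = pseudo_r2(summaries, mode=mode)
            X = np.column_stack([s.table["beta"] for s in summaries])
            mat = np.corrcoef(X.T) if mode == "correlation" else np.cov(X.T)
            lam = np.linalg.eigvalsh(mat)
            assert r.pseudo_r2_beta == pytest.approx(lam[-1] / lam.sum(),
                                                     abs=1e-10)

    def test_pair_degeneracy_identity(self, rng):
        """For two variables the first-PC fraction equals (1 + |r|) / 2."""
        a = make_summary(rng, name="a")
        b = make_summary(rng, name="b")
        r = qtl_correlation(a, b).pearson_beta
        X = np.column_stack([a.table["beta"], b.table["beta"]])
        lam = np.linalg.eigvalsh(np.corrcoef(X.T))
        assert lam[-1] / lam.sum() == pytest.approx((1 + abs(r)) / 2, abs=1e-12)

    def test_degenerate_column_named(self, rng):
        a = make_summary(rng, name="flat", beta=np.ones(50))
        b = make_summary(rng, name="b")
        c = make_summary(rng, name="c")
        with pytest.raises(ValueError, match="flat"):
            pseudo_r2([a, b, c])


class TestCoreHaplotype:
    def test_identical_ranking_gives_common_top(self, rng):
        beta = np.linspace(1, 100, 100)
        summaries = [make_summary(rng, n=100, name=nm, beta=beta)
                     for nm in "ab"]
        core = core_haplotype(summaries, q=0.05)
        assert len(core) == 5
        assert set(core.variant_ids) == {f"v{i}" for i in range(95, 100)}

    def test_reversed_rankings_give_empty_intersection(self, rng):
        beta = np.linspace(1, 100, 100)
        a = make_summary(rng, n=100, name="a", beta=beta)
        b = make_summary(rng, n=100, name="b", beta=beta[::-1])
        core = core_haplotype([a, b], q=0.05)
        assert len(core) == 0

    def test_q_one_returns_universe_and_monotone_in_q(self, rng):
        summaries = [make_summary(rng, name=nm) for nm in "ab"]
        full = core_haplotype(summaries, q=1.0)
        assert len(full) == 50
        sizes = [len(core_haplotype(summaries, q=q))
                 for q in (0.05, 0.1, 0.25, 0.5, 1.0)]
        assert sizes == sorted(sizes)

    def test_membership_flags_consistent(self, rng):
        summaries = [make_summary(rng, name=nm) for nm in "abc"]
        core = core_haplotype(summaries, q=0.2)
        memb = core.membership
        in_all = memb.all(axis=1)
        assert sorted(memb.index[in_all]) == core.variant_ids


class TestLdR2:
    def _geno(self, rng, n=200):
        d = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        d[:, 1] = d[:, 0]
        d[:, 2] = 2.0 - d[:, 0]
        variants = [VariantRecord(f"v{j}", "1", j + 1, "A", "C")
                    for j in range(3)]
        return GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)

    def test_copy_and_repulsion_give_one(self, rng):
        g = self._geno(rng)
        assert ld_r2(g, "v0", "v1") == pytest.approx(1.0)
        assert ld_r2(g, "v0", "v2") == pytest.approx(1.0)  # sign-invariant

    def test_independent_pairs_near_zero(self, rng):
        n = 700
        r2s = []
        for _ in range(300):
            a = rng.binomial(2, 0.3, n).astype(float)
            b = rng.binomial(2, 0.3, n).astype(float)
            g = GenotypeMatrix([f"s{i}" for i in range(n)],
                               [VariantRecord("a", "1", 1, "A", "C"),
                                VariantRecord("b", "1", 2, "A", "C")],
                               np.column_stack([a, b]))
            r2s.append(ld_r2(g, "a", "b"))
        assert np.mean(np.array(r2s) < 0.01) > 0.9

    def test_monomorphic_rejected(self, rng):
        g = self._geno(rng)
        g.dosage[:, 0] = 1.0
        with pytest.raises(ValueError):
            ld_r2(g, "v0", "v1")


class TestVariantPeakOverlap:
    def test_inclusive_boundaries(self):
        ps = PeakSet([Peak("pk", "22", 100, 200)], "ATAC")
        vs = [VariantRecord("at_start", "22", 100, "A", "C"),
              VariantRecord("at_end", "22", 200, "A", "C"),
              VariantRecord("past_end", "22", 201, "A", "C"),
              VariantRecord("other_chrom", "1", 150, "A", "C")]
        out = variant_peak_overlap(vs, [ps])
        assert out["at_start"] == [("ATAC", "pk")]
        assert out["at_end"] == [("ATAC", "pk")]
        assert out["past_end"] == []
        assert out["other_chrom"] == []

    def test_matches_quadratic_oracle(self, rng):
        peaks = []
        for i in range(200):
            start = int(rng.integers(1, 10**6))
            peaks.append(Peak(f"p{i}", "22", start,
                              start + int(rng.integers(1, 5000))))
        ps = PeakSet(peaks, "H3K4Me1")
        vs = [VariantRecord(f"v{i}", "22", int(rng.integers(1, 10**6)),
                            "A", "C") for i in range(2000)]
        out = variant_peak_overlap(vs, [ps])
        for v in vs:
            expected = sorted(("H3K4Me1", p.name) for p in peaks
                              if p.start <= v.pos <= p.end)
            assert out[v.id] == expected


class TestVariantDensityPercentile:
    def test_equal_density_gives_zero(self):
        pos = np.arange(100, 200)
        pct = variant_density_percentile(pos, (100, 199), [100] * 50, 100)
        assert pct == 0.0

    def test_denser_than_all_gives_hundred(self):
        pos = np.arange(0, 1000)
        pct = variant_density_percentile(pos, (0, 99), [5] * 50, 100)
        assert pct == 100.0

    def test_uniform_null_is_central(self, rng):
        inside = 0
        for _ in range(100):
            pos = rng.integers(0, 100_000, size=2000)
            counts = np.histogram(pos, bins=np.arange(0, 100_001, 1000))[0]
            focus = (50_000, 50_999)
            pct = variant_density_percentile(pos, focus, counts, 1000)
            if 5 <= pct <= 95:
                inside += 1
        assert inside >= 90
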