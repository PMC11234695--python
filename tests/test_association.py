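"""GRM construction, REML variance components and mixed-model association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coregqtl.association import (Grm, MixedAssociationScan, PolygenicModel,
                                  bonferroni_threshold, compute_grm,
                                  conditional_scan, format_threshold, mlma)
from coregqtl.datatypes import GenotypeMatrix, VariantRecord
from coregqtl.simulate import SimConfig, simulate_genotypes


def random_genotypes(rng, n=60, m=100):
    d = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
    variants = [VariantRecord(f"v{j}", str(1 + j // 50), j + 1, "A", "C")
                for j in range(m)]
    return GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)


def polygenic_y(grm, h2, rng):
    w, U = np.linalg.eigh(grm.matrix)
    a = U @ (np.sqrt(np.clip(w, 0, None) * h2) * rng.standard_normal(len(w)))
    return a + rng.normal(0, np.sqrt(1 - h2), grm.n)


class TestGrm:
    def test_identical_samples_share_relatedness(self, rng):
        g = random_genotypes(rng, n=10, m=200)
        g.dosage[1] = g.dosage[0]
        grm = compute_grm(g)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0], abs=1e-12)
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[1, 1], abs=1e-12)

    def test_brute_force_oracle(self, rng):
        g = random_genotypes(rng, n=20, m=100)
        grm = compute_grm(g)
        d = g.dosage
        p = d.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        d, p = d[:, keep], p[keep]
        expected = np.zeros((20, 20))
        for i in range(20):
            for k in range(20):
                z_i = (d[i] - 2 * p) / np.sqrt(2 * p * (1 - p))
                z_k = (d[k] - 2 * p) / np.sqrt(2 * p * (1 - p))
                expected[i, k] = np.mean(z_i * z_k)
        np.testing.assert_allclose(grm.matrix, expected, atol=1e-12)

    def test_diagonal_near_one(self, small_sim):
        g, _ = small_sim
        grm = compute_grm(g)
        assert grm.matrix.diagonal().mean() == pytest.approx(1.0, abs=0.15)

    def test_chromosome_exclusion_is_complement(self, rng):
        g = random_genotypes(rng, n=30, m=100)  # two chromosomes of 50
        loco = compute_grm(g, exclude="1")
        manual = compute_grm(g.subset_variants(
            np.array([v.chrom != "1" for v in g.variants])))
        np.testing.assert_allclose(loco.matrix, manual.matrix, atol=1e-14)
        assert loco.n_variants_used == manual.n_variants_used


class TestReml:
    def test_h2_recovery(self):
        """Mean estimate near the simulated heritability."""
        ests = []
        for seed in range(25):
            rng = np.random.default_rng(500 + seed)
            g = random_genotypes(rng, n=300, m=800)
            grm = compute_grm(g)
            y = polygenic_y(grm, 0.4, rng)
            ests.append(PolygenicModel(y, grm).fit().h2)
        assert abs(np.mean(ests) - 0.4) < 0.05

    def test_null_h2_near_zero(self):
        ests, ps = [], []
        for seed in range(30):
            rng = np.random.default_rng(800 + seed)
            g = random_genotypes(rng, n=150, m=400)
            grm = compute_grm(g)
            y = rng.normal(size=grm.n)
            fit = PolygenicModel(y, grm).fit()
            ests.append(fit.h2)
            ps.append(fit.lrt_p)
        assert np.median(ests) < 0.05
        assert np.mean(np.array(ps) < 0.5) < 0.75  # p not piled at small values

    def test_constant_phenotype_rejected(self, rng):
        g = random_genotypes(rng, n=20, m=50)
        grm = compute_grm(g)
        with pytest.raises(ValueError):
            PolygenicModel(np.ones(20), grm)

    def test_scaling_invariance(self, rng):
        g = random_genotypes(rng, n=120, m=300)
        grm = compute_grm(g)
        y = polygenic_y(grm, 0.5, rng)
        a = PolygenicModel(y, grm).fit()
        b = PolygenicModel(10.0 * y, grm).fit()
        assert b.h2 == pytest.approx(a.h2, abs=1e-4)
        assert b.sigma2_g == pytest.approx(100.0 * a.sigma2_g, rel=1e-3)


class TestMlma:
    def test_identity_grm_collapses_to_ols(self, rng):
        g = random_genotypes(rng, n=80, m=40)
        grm = Grm(g.samples, np.eye(80), 1)
        y = rng.normal(size=80) + 0.5 * g.dosage[:, 7]
        res = mlma(y, g, grm)
        for j in [0, 7, 20]:
            slope = stats.linregress(g.dosage[:, j], y).slope
            assert res.table.loc[j, "beta"] == pytest.approx(slope, abs=1e-8)

    def test_wald_relation_holds(self, rng, small_sim):
        g, _ = small_sim
        grm = compute_grm(g)
        y = rng.normal(size=g.n_samples)
        res = mlma(y, g, grm)
        t = res.summary_table.tested()
        z = (t["beta"] / t["se"]).abs()
        np.testing.assert_allclose(t["p"], 2 * stats.norm.sf(z), rtol=1e-10)

    def test_shift_and_allele_flip_invariance(self, rng):
        g = random_genotypes(rng, n=100, m=30)
        grm = compute_grm(g)
        y = rng.normal(size=100) + 0.4 * g.dosage[:, 3]
        a = mlma(y, g, grm)
        b = mlma(y + 100.0, g, grm)
        np.testing.assert_allclose(b.table["beta"], a.table["beta"], atol=1e-8)
        np.testing.assert_allclose(b.table["p"], a.table["p"], rtol=1e-6)
        gf = GenotypeMatrix(list(g.samples), list(g.variants), 2.0 - g.dosage)
        c = mlma(y, gf, grm)
        np.testing.assert_allclose(c.table["beta"], -a.table["beta"], atol=1e-8)
        np.testing.assert_allclose(c.table["p"], a.table["p"], rtol=1e-6)

    def test_monomorphic_variant_flagged_not_dropped(self, rng):
        g = random_genotypes(rng, n=50, m=10)
        g.dosage[:, 4] = 2.0
        grm = compute_grm(g)
        res = mlma(rng.normal(size=50), g, grm)
        row = res.table.iloc[4]
        assert row["status"] == "monomorphic"
        assert np.isnan(row["p"])
        assert len(res.table) == 10

    def test_planted_effect_recovered(self):
        """Causal beta within 2 SE in most seeds, detected genome-wide."""
        hits, within = 0, 0
        n_seeds = 12
        for seed in range(n_seeds):
            cfg = SimConfig(n_animals=600, n_variants=600, seed=2000 + seed,
                            ld_block_size=30)
            g, truth = simulate_genotypes(cfg)
            rng = np.random.default_rng(77 + seed)
            dose = g.dosage_of(truth.causal_variant_ids[0])
            # leave-one-chromosome-out GRM so the tested signal is neither
            # absorbed by the polygenic term (proximal contamination) nor
            # re-generated by the polygenic background
            loco = compute_grm(g, exclude="22")
            y = 0.56 * dose + polygenic_y(loco, 0.4, rng)
            res = mlma(y, g, loco)
            row = res.table[res.table["id"] == truth.causal_variant_ids[0]].iloc[0]
            if row["p"] < bonferroni_threshold(0.05, 631896):
                hits += 1
            if abs(row["beta"] - 0.56) < 2 * row["se"]:
                within += 1
        assert hits >= 0.9 * n_seeds
        assert within >= 0.9 * n_seeds


class TestConditionalScan:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimConfig(n_animals=500, n_variants=500, seed=31)
        g, truth = simulate_genotypes(cfg)
        rng = np.random.default_rng(31)
        dose = g.dosage_of(truth.causal_variant_ids[0])
        loco = compute_grm(g, exclude="22")
        y = 0.56 * dose + polygenic_y(loco, 0.3, rng)
        return g, truth, loco, y

    def test_conditioning_on_causal_absorbs_core(self, planted):
        g, truth, grm, y = planted
        causal = truth.causal_variant_ids[0]
        res = conditional_scan(y, g, grm, condition_on=causal)
        core = res.table[res.table["id"].isin(set(truth.core_haplotype_ids)
                                              - {causal})]
        p = core["p"].to_numpy()
        assert np.all(np.isnan(p) | (p > 1e-3))
        cond_row = res.table[res.table["id"] == causal].iloc[0]
        assert cond_row["status"] == "conditioned"

    def test_conditioning_on_unlinked_variant_changes_little(self, planted):
        g, truth, grm, y = planted
        causal = truth.causal_variant_ids[0]
        base = mlma(y, g, grm)
        logp0 = -np.log10(base.table.loc[base.table["id"] == causal, "p"].iloc[0])
        unlinked = g.variants[2].id  # far block
        res = conditional_scan(y, g, grm, condition_on=unlinked)
        logp1 = -np.log10(res.table.loc[res.table["id"] == causal, "p"].iloc[0])
        assert abs(logp1 - logp0) / logp0 < 0.10

    def test_partial_ld_reduces_but_keeps_signal(self, planted):
        from coregqtl.coreg import ld_r2
        g, truth, grm, y = planted
        causal = truth.causal_variant_ids[0]
        base = mlma(y, g, grm)
        logp0 = -np.log10(base.table.loc[base.table["id"] == causal, "p"].iloc[0])
        # pick a variant moderately linked to the causal one
        cands = [(v.id, ld_r2(g, causal, v.id)) for v in g.variants
                 if v.id not in truth.core_haplotype_ids and v.maf > 0.05]
        vid, r2 = min(cands, key=lambda t: abs(t[1] - 0.3))
        assert 0.1 < r2 < 0.6
        res = conditional_scan(y, g, grm, condition_on=vid)
        logp1 = -np.log10(res.table.loc[res.table["id"] == causal, "p"].iloc[0])
        assert logp1 < logp0          # attenuated ...
        assert logp1 > -np.log10(1e-3)  # ... but still clearly significant

    def test_unknown_variant_raises(self, planted):
        g, truth, grm, y = planted
        with pytest.raises(KeyError):
            conditional_scan(y, g, grm, condition_on="nope")


class TestBonferroni:
    def test_values(self):
        assert format_threshold(bonferroni_threshold(0.05, 631896)) == pytest.approx(7.9e-8)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        assert bonferroni_threshold(0.05, 10**6) == pytest.approx(5.0e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
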