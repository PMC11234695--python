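"""Depth normalisation, peak filters, residual phenotypes, PCA exclusion and
the expression-normalisation surrogate."""

import numpy as np
import pytest

from coregqtl.chromatin import (broadcast_consensus_input, depth_normalize,
                                expression_normalize, filter_peaks,
                                pca_outliers, residual_phenotype)
from coregqtl.datatypes import CountMatrix, Peak, PeakSet
from coregqtl.protein import sample_skewness


def make_cm(counts, prefix="p"):
    counts = np.asarray(counts)
    return CountMatrix([f"{prefix}{i}" for i in range(counts.shape[0])],
                       [f"s{j}" for j in range(counts.shape[1])], counts)


class TestDepthNormalize:
    def test_equal_totals_identity(self):
        cm = make_cm([[3, 3], [7, 7]])
        cN, df = depth_normalize(cm)
        np.testing.assert_allclose(cN, cm.counts)
        np.testing.assert_allclose(df.f, 1.0)

    def test_worked_example(self):
        # t = [6, 12], f = [2/3, 4/3], C/f = [[3, 3], [6, 6]]
        cm = make_cm([[2, 4], [4, 8]])
        cN, df = depth_normalize(cm)
        np.testing.assert_allclose(df.t, [6, 12])
        np.testing.assert_allclose(df.f, [2 / 3, 4 / 3])
        np.testing.assert_allclose(cN, [[3, 3], [6, 6]])

    def test_column_sums_equalized(self, rng):
        cm = make_cm(rng.poisson(50, size=(40, 12)) + 1)
        cN, df = depth_normalize(cm)
        sums = cN.sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], atol=1e-9)
        assert df.f.mean() == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_sample_named(self):
        cm = make_cm([[0, 5], [0, 5]])
        with pytest.raises(ValueError, match="s0"):
            depth_normalize(cm)


def peakset_for(cm, lengths, assay="ATAC"):
    peaks = [Peak(name, "22", 1000 * (i + 1), 1000 * (i + 1) + L - 1)
             for i, (name, L) in enumerate(zip(cm.peak_names, lengths))]
    return PeakSet(peaks, assay)


class TestFilterPeaks:
    def test_all_equal_nothing_removed(self):
        cm = make_cm(np.full((10, 4), 20))
        im = make_cm(np.full((10, 4), 10))
        ps = peakset_for(cm, [500] * 10)
        assert filter_peaks(cm, im, ps) == cm.peak_names

    def test_planted_input_pileup_removed(self, rng):
        n = 200
        chip = rng.poisson(100, size=(n, 6))
        inp = rng.poisson(50, size=(n, 6))
        inp[37] *= 20  # reference-artefact pile-up
        cm, im = make_cm(chip), make_cm(inp)
        ps = peakset_for(cm, rng.integers(400, 600, n))
        kept = filter_peaks(cm, im, ps, low_percentile=0.0)
        assert set(cm.peak_names) - set(kept) == {"p37"}

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 40))
            chip = rng.poisson(rng.uniform(5, 200), size=(n, 3))
            inp = rng.poisson(rng.uniform(5, 100), size=(n, 3))
            lengths = rng.integers(100, 2000, size=n)
            cm, im = make_cm(chip), make_cm(inp)
            ps = peakset_for(cm, lengths)
            kept = filter_peaks(cm, im, ps)
            # independent two-pass reimplementation
            adj = chip.sum(axis=1) / lengths
            adj_in = inp.sum(axis=1) / lengths
            low = adj < np.percentile(adj, 1.0)
            piled = adj_in > 5.0 * adj_in.mean()
            expected = [f"p{i}" for i in range(n) if not (low[i] or piled[i])]
            assert kept == expected

    def test_missing_length_raises(self):
        cm = make_cm(np.ones((2, 3)))
        im = make_cm(np.ones((2, 3)))
        ps = PeakSet([Peak("p0", "22", 1, 100)], "ATAC")
        with pytest.raises(KeyError):
            filter_peaks(cm, im, ps)


class TestResidualPhenotype:
    def test_perfect_linear_fit_zero_residuals(self, rng):
        x = rng.uniform(1, 5, size=(4, 10))
        yln = 0.3 + 1.7 * np.log(x + 1)
        c = np.exp(yln) - 1
        ph = residual_phenotype(c, x, [f"p{i}" for i in range(4)],
                                [f"s{j}" for j in range(10)])
        np.testing.assert_allclose(ph.residuals, 0.0, atol=1e-10)

    def test_constant_input_falls_back_to_centred_counts(self, rng):
        c = rng.poisson(40, size=(3, 8)).astype(float)
        x = np.full((3, 8), 7.0)
        ph = residual_phenotype(c, x, ["a", "b", "c"], [f"s{j}" for j in range(8)])
        assert ph.intercept_only.all()
        logc = np.log(c + 1)
        np.testing.assert_allclose(ph.residuals,
                                   logc - logc.mean(axis=1, keepdims=True),
                                   atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        C = rng.poisson(60, size=(50, 30)).astype(float)
        I = rng.poisson(40, size=(50, 30)).astype(float)
        ph = residual_phenotype(C, I, [f"p{i}" for i in range(50)],
                                [f"s{j}" for j in range(30)])
        y = np.log(C + 1)
        x = np.log(I + 1)
        for i in range(50):
            X = np.column_stack([np.ones(30), x[i]])
            coef = np.linalg.solve(X.T @ X, X.T @ y[i])
            np.testing.assert_allclose(ph.intercepts[i], coef[0], atol=1e-10)
            np.testing.assert_allclose(ph.slopes[i], coef[1], atol=1e-10)
            np.testing.assert_allclose(ph.residuals[i], y[i] - X @ coef,
                                       atol=1e-10)
        assert np.max(np.abs(ph.residuals.mean(axis=1))) < 1e-9

    def test_depth_scaling_invariance(self, rng):
        """Multiplying one sample's ChIP and input counts by a common factor
        leaves the final residual phenotype unchanged (to 1e-8): the depth
        factor of that sample scales by the same constant and cancels. The
        normalisation reference is pinned so it does not drift with the
        rescaled totals."""
        C = rng.poisson(80, size=(20, 12)).astype(float)
        I = rng.poisson(50, size=(20, 12)).astype(float)
        names = [f"p{i}" for i in range(20)]
        ids = [f"s{j}" for j in range(12)]
        ref_c = C.sum(axis=0).mean()
        ref_i = I.sum(axis=0).mean()

        def run(c, i):
            cN, _ = depth_normalize(make_cm(c), reference_depth=ref_c)
            iN, _ = depth_normalize(make_cm(i), reference_depth=ref_i)
            return residual_phenotype(cN, iN, names, ids).residuals

        base = run(C, I)
        C2, I2 = C.copy(), I.copy()
        C2[:, 3] *= 4.0
        I2[:, 3] *= 4.0
        np.testing.assert_allclose(run(C2, I2), base, atol=1e-8)

    def test_consensus_input_broadcast(self, rng):
        consensus = rng.poisson(30, size=12).astype(float)
        inp = broadcast_consensus_input(consensus, 9)
        assert inp.shape == (12, 9)
        c = rng.poisson(50, size=(12, 9)).astype(float)
        ph = residual_phenotype(c, inp, [f"p{i}" for i in range(12)],
                                [f"s{j}" for j in range(9)])
        assert ph.intercept_only.all()


class TestPcaOutliers:
    def test_identical_rows_no_exclusions(self):
        m = np.tile([1.0, 2.0, 3.0], (8, 1))
        assert pca_outliers(m, n_pcs=2, sd_threshold=4.0) == []

    def test_planted_outlier_found(self, rng):
        m = rng.normal(size=(40, 15))
        direction = rng.normal(size=15)
        direction /= np.linalg.norm(direction)
        m[13] += 10 * m.std() * np.sqrt(15) * direction
        out = pca_outliers(m, n_pcs=3, sd_threshold=4.0)
        assert out == [13]

    def test_scale_invariance(self, rng):
        m = rng.normal(size=(30, 10))
        m[4] += 8 * np.ones(10)
        a = pca_outliers(m, n_pcs=4, sd_threshold=3.0)
        b = pca_outliers(1000.0 * m, n_pcs=4, sd_threshold=3.0)
        assert a == b

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pca_outliers(np.ones((2, 5)), 1, 4.0)


class TestExpressionNormalize:
    def test_equal_counts_unit_size_factors(self):
        K = np.full((5, 4), 16.0)
        norm, sf = expression_normalize(K)
        np.testing.assert_allclose(sf, 1.0)
        np.testing.assert_allclose(norm, np.log2(17.0))

    def test_doubled_library_doubles_size_factor(self, rng):
        K = rng.poisson(100, size=(300, 6)).astype(float) + 1
        K2 = K.copy()
        K2[:, 2] *= 2
        _, sf = expression_normalize(K2)
        assert sf[2] / np.median(np.delete(sf, 2)) == pytest.approx(2.0, rel=0.05)

    def test_reduces_skew_of_lognormal_counts(self, rng):
        mu = rng.normal(4, 1, size=400)
        K = rng.poisson(np.exp(mu[:, None] + rng.normal(0, 0.2, (400, 20))))
        K = K + (K.sum(axis=1, keepdims=True) == 0)
        norm, _ = expression_normalize(K.astype(float))
        raw_skew = sample_skewness(K.mean(axis=1))
        norm_skew = sample_skewness(norm.mean(axis=1))
        assert abs(norm_skew) < abs(raw_skew)

    def test_all_zero_gene_rejected(self):
        K = np.ones((3, 4))
        K[1] = 0
        with pytest.raises(ValueError):
            expression_normalize(K)
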