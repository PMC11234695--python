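"""Chromatin-openness phenotypes from ChIP/ATAC read-count matrices.

The pipeline: per-sample read-depth normalisation (each sample's counts are
divided by its total-count factor relative to the mean sample), peak-level
quality filters (length-adjusted count below the 1st percentile, or input
pile-up over 5x the average), a per-peak OLS of log counts on log input
whose residuals are the QTL phenotype, and PCA-based sample exclusion.
A median-of-ratios + log normalisation stands in for the variance-stabilising
transformation on expression counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, PeakSet


@dataclass
class DepthFactors:
    """Per-sample totals ``t`` and relative depth factors ``f = t / mean(t)``."""

    sample_ids: list[str]
    t: np.ndarray
    f: np.ndarray


@dataclass
class ChromPhenotype:
    """Per-peak input-regression residuals: the hQTL/caQTL phenotype.

    ``residuals[i, j]`` is peak i's residual for sample j; each row has mean
    zero (OLS with intercept). ``intercept_only`` flags peaks whose input was
    constant, where the residuals are simply the centred log counts.
    """

    peak_names: list[str]
    sample_ids: list[str]
    residuals: np.ndarray
    slopes: np.ndarray
    intercepts: np.ndarray
    intercept_only: np.ndarray

    def phenotype(self, peak_name: str) -> np.ndarray:
        return self.residuals[self.peak_names.index(peak_name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.residuals, index=self.peak_names,
                            columns=self.sample_ids)


def depth_normalize(cm: CountMatrix,
                    reference_depth: float | None = None) -> tuple[np.ndarray, DepthFactors]:
    """Divide each sample's counts by its relative read-depth factor.

    ``t_j`` is sample j's total count, ``f_j = t_j / mean(t)``, and the
    normalised matrix is ``C / f`` columnwise, so every sample's adjusted
    total equals the mean raw total. The reference ``mean(t)`` is an
    arbitrary scale constant; passing ``reference_depth`` pins it, which
    makes the normalisation exactly invariant to rescaling any single
    sample's raw counts.
    """
    C = np.asarray(cm.counts, dtype=float)
    t = C.sum(axis=0)
    zero = np.where(t == 0)[0]
    if zero.size:
        raise ValueError(f"sample {cm.sample_ids[zero[0]]!r} has zero total reads")
    ref = float(t.mean()) if reference_depth is None else float(reference_depth)
    f = t / ref
    return C / f, DepthFactors(list(cm.sample_ids), t, f)


def filter_peaks(cm: CountMatrix, input_cm: CountMatrix, peaks: PeakSet,
                 low_percentile: float = 1.0,
                 input_fold: float = 5.0) -> list[str]:
    """Peak quality filters applied to the unfiltered set simultaneously.

    A peak's length-adjusted count is its total reads divided by its length
    in bases. Removed: peaks strictly below the ``low_percentile`` of the
    length-adjusted ChIP counts, and peaks whose length-adjusted *input*
    count exceeds ``input_fold`` times the mean (reference-artefact pile-ups).
    Survivors are returned in their original order.
    """
    if cm.peak_names != input_cm.peak_names:
        raise ValueError("ChIP and input matrices must share peak names in order")
    lengths = peaks.lengths()
    missing = [p for p in cm.peak_names if p not in lengths]
    if missing:
        raise KeyError(f"no peak length for {missing[0]!r}")
    length_vec = np.array([lengths[p] for p in cm.peak_names], dtype=float)
    adj = np.asarray(cm.counts, dtype=float).sum(axis=1) / length_vec
    adj_in = np.asarray(input_cm.counts, dtype=float).sum(axis=1) / length_vec
    cutoff = np.percentile(adj, low_percentile)  # linear interpolation
    low = adj < cutoff
    piled = adj_in > input_fold * adj_in.mean()
    keep = ~(low | piled)
    return [p for p, k in zip(cm.peak_names, keep) if k]


def residual_phenotype(c_norm: np.ndarray, i_norm: np.ndarray,
                       peak_names: list[str],
                       sample_ids: list[str]) -> ChromPhenotype:
    """Per-peak OLS of ``log(C_norm + 1)`` on ``log(I_norm + 1)``.

    The residual vector of each peak's regression is its chromatin-openness
    phenotype. Peaks with a constant input covariate fall back to an
    intercept-only model (residuals = centred log counts) and are flagged.
    Natural logs throughout.
    """
    C = np.asarray(c_norm, dtype=float)
    I = np.asarray(i_norm, dtype=float)
    if C.shape != I.shape:
        raise ValueError("count and input matrices must have matching shapes")
    if C.shape[1] < 3:
        raise ValueError("need at least 3 samples to fit the per-peak regression")
    y = np.log(C + 1.0)
    x = np.log(I + 1.0)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    xc = x - xm
    yc = y - ym
    sxx = np.sum(xc * xc, axis=1)
    # rounding in the row mean leaves sxx ~ eps^2 for constant covariates
    tol = x.shape[1] * (100 * np.finfo(float).eps
                        * (1.0 + np.abs(x).max(axis=1))) ** 2
    constant = sxx <= tol
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(constant, 0.0, np.sum(xc * yc, axis=1) / np.where(sxx == 0, 1, sxx))
    a = ym[:, 0] - b * xm[:, 0]
    resid = yc - b[:, None] * xc
    return ChromPhenotype(list(peak_names), list(sample_ids), resid, b, a, constant)


def chromatin_phenotypes(cm: CountMatrix, input_cm: CountMatrix) -> ChromPhenotype:
    """Depth-normalise ChIP and input counts, then fit the residual phenotype."""
    cN, _ = depth_normalize(cm)
    iN, _ = depth_normalize(input_cm)
    return residual_phenotype(cN, iN, cm.peak_names, cm.sample_ids)


def broadcast_consensus_input(input_column: np.ndarray, n_samples: int) -> np.ndarray:
    """Represent a consensus (pooled) input as one column repeated per sample.

    Used for assays without per-sample input: the input covariate is then
    constant within each peak, so the residual phenotype reduces to centred
    log counts per peak.
    """
    col = np.asarray(input_column, dtype=float).reshape(-1, 1)
    return np.repeat(col, n_samples, axis=1)


def pca_outliers(m: np.ndarray, n_pcs: int = 7, sd_threshold: float = 4.0,
                 sample_ids: list[str] | None = None) -> list:
    """Samples whose score on any leading PC is > ``sd_threshold`` SDs out.

    Single pass on centred (unscaled) data: compute PC scores, flag samples
    with ``|score - mean| > sd_threshold * SD`` on any of the first
    ``n_pcs`` components. Returns excluded sample ids (or indices).
    """
    X = np.asarray(m, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for PCA outlier detection")
    if n_pcs > min(n - 1, X.shape[1]):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(samples-1, features)")
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    sd = scores.std(axis=0, ddof=1)
    mean = scores.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        flag = np.any(np.abs(scores - mean) > sd_threshold * np.where(sd == 0, np.inf, sd),
                      axis=1)
    idx = np.where(flag)[0]
    if sample_ids is not None:
        return [sample_ids[i] for i in idx]
    return list(idx)


def deseq_size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (genes x samples)."""
    K = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(K)
    finite = np.all(np.isfinite(logs), axis=1)
    if not finite.any():
        raise ValueError("no gene with nonzero counts in every sample")
    ref = logs[finite].mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs[finite] - ref, axis=0))
    return sf


def expression_normalize(counts: np.ndarray, gene_index: int | None = None,
                         gene_lengths: np.ndarray | None = None):
    """Variance-stabilising surrogate for expression counts.

    Computes median-of-ratios size factors and returns
    ``log2(count / size_factor + 1)``; a documented surrogate for the exact
    DESeq2 VST, isolated here so another backend can be swapped in. When
    ``gene_index`` is given, only that gene's normalised vector is returned.
    With ``gene_lengths``, TPM values are also computed.
    """
    K = np.asarray(counts, dtype=float)
    if np.any(np.all(K == 0, axis=1)):
        bad = int(np.where(np.all(K == 0, axis=1))[0][0])
        raise ValueError(f"gene {bad} has zero counts in all samples")
    sf = deseq_size_factors(K)
    norm = np.log2(K / sf + 1.0)
    tpm = None
    if gene_lengths is not None:
        L = np.asarray(gene_lengths, dtype=float).reshape(-1, 1)
        rate = K / L
        tpm = rate / rate.sum(axis=0) * 1e6
    if gene_index is not None:
        return (norm[gene_index], sf) if tpm is None else (norm[gene_index], sf, tpm[gene_index])
    return (norm, sf) if tpm is None else (norm, sf, tpm)
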