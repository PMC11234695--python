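"""Co-localisation of QTL signals across molecular layers.

Given per-variant association summaries for two or more QTL (protein,
expression, histone, chromatin accessibility), this module measures shared
genetic architecture: Pearson/Spearman correlations of allele effects and of
-log10 p-values within a window, the PCA pseudo-R2 (fraction of variance of a
triplet of effect vectors captured by their first principal component), the
core haplotype (variants simultaneously in the top q fraction by |beta| of
every layer), pairwise LD R2, variant-peak containment, and variant-density
percentiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .datatypes import GenotypeMatrix, PeakSet, QtlSummary, VariantRecord


def harmonize(a: QtlSummary, b: QtlSummary) -> pd.DataFrame:
    """Inner-join two summaries on variant id with allele orientation aligned.

    When b's ref/alt are swapped relative to a, b's beta sign is flipped;
    variants whose alleles do not match either orientation, or with NA in
    either summary, are dropped. Columns: id, pos, beta_a, beta_b, p_a, p_b.
    """
    ta = a.tested()[["id", "chrom", "pos", "ref", "alt", "beta", "p"]]
    tb = b.tested()[["id", "ref", "alt", "beta", "p"]]
    m = ta.merge(tb, on="id", suffixes=("_a", "_b"))
    same = (m["ref_a"] == m["ref_b"]) & (m["alt_a"] == m["alt_b"])
    flipped = (m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])
    m = m[same | flipped].copy()
    flip = ((m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])).to_numpy()
    m["beta_b"] = np.where(flip, -m["beta_b"], m["beta_b"])
    return m[["id", "chrom", "pos", "beta_a", "beta_b", "p_a", "p_b"]]


@dataclass
class CoregResult:
    """Pairwise (or triplet) co-regulation statistics within a window."""

    qtl_names: tuple
    window: tuple | None
    n_shared_variants: int
    pearson_beta: float = float("nan")
    spearman_beta: float = float("nan")
    pearson_logp: float = float("nan")
    spearman_logp: float = float("nan")
    pseudo_r2_beta: float = float("nan")
    pseudo_r2_logp: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "qtl": "+".join(self.qtl_names),
            "window": ("{}:{}-{}".format(*self.window) if self.window else ""),
            "n": self.n_shared_variants,
            "pearson_beta": self.pearson_beta,
            "spearman_beta": self.spearman_beta,
            "pearson_logp": self.pearson_logp,
            "spearman_logp": self.spearman_logp,
            "pseudo_r2_beta": self.pseudo_r2_beta,
            "pseudo_r2_logp": self.pseudo_r2_logp,
        }


def _window(qs: QtlSummary, window) -> QtlSummary:
    if window is None:
        return qs
    chrom, start, end = window
    return qs.in_window(chrom, start, end)


def qtl_correlation(a: QtlSummary, b: QtlSummary,
                    window: tuple[str, int, int] | None = None) -> CoregResult:
    """Pearson and Spearman correlations between two QTL summaries.

    Computed over shared variants in ``window`` for both the beta allele
    effects and the -log10 p-values, after allele harmonisation.
    """
    m = harmonize(_window(a, window), _window(b, window))
    n = len(m)
    if n < 3:
        raise ValueError(f"only {n} shared variants in window; need >= 3")
    lpa = -np.log10(m["p_a"].to_numpy())
    lpb = -np.log10(m["p_b"].to_numpy())
    return CoregResult(
        (a.name, b.name), window, n,
        pearson_beta=float(stats.pearsonr(m["beta_a"], m["beta_b"]).statistic),
        spearman_beta=float(stats.spearmanr(m["beta_a"], m["beta_b"]).statistic),
        pearson_logp=float(stats.pearsonr(lpa, lpb).statistic),
        spearman_logp=float(stats.spearmanr(lpa, lpb).statistic),
    )


def _align_three(summaries, window) -> pd.DataFrame:
    a, b, c = summaries
    m_ab = harmonize(_window(a, window), _window(b, window))
    m_ac = harmonize(_window(a, window), _window(c, window))
    m = m_ab.merge(m_ac[["id", "beta_b", "p_b"]].rename(
        columns={"beta_b": "beta_c", "p_b": "p_c"}), on="id")
    return m


def pseudo_r2(summaries: list[QtlSummary],
              window: tuple[str, int, int] | None = None,
              mode: str = "correlation") -> CoregResult:
    """Fraction of variance of three QTL effect vectors on their first PC.

    Eigendecomposition of the 3x3 correlation (default) or covariance matrix
    of the harmonised beta vectors (and of the -log10 p vectors); returns
    lambda_1 / sum(lambda). With standardized variables the value lies in
    [1/3, 1]: 1 for rank-one (perfectly co-regulated) signals, 1/3 for
    mutually uncorrelated ones.
    """
    if len(summaries) != 3:
        raise ValueError("pseudo_r2 requires exactly 3 QTL summaries")
    if mode not in ("correlation", "covariance"):
        raise ValueError("mode must be 'correlation' or 'covariance'")
    m = _align_three(summaries, window)
    if len(m) < 4:
        raise ValueError(f"only {len(m)} shared variants; need >= 4")
    names = tuple(s.name for s in summaries)
    out = CoregResult(names, window, len(m))
    for which, cols in (("beta", ["beta_a", "beta_b", "beta_c"]),
                        ("logp", ["p_a", "p_b", "p_c"])):
        X = m[cols].to_numpy(dtype=float)
        if which == "logp":
            X = -np.log10(X)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            bad = names[int(np.where(sd == 0)[0][0])]
            raise ValueError(f"degenerate (zero-variance) column for {bad!r}")
        mat = np.corrcoef(X, rowvar=False) if mode == "correlation" else np.cov(X, rowvar=False)
        lam = np.linalg.eigvalsh(mat)
        frac = float(lam[-1] / lam.sum())
        setattr(out, f"pseudo_r2_{which}", frac)
    return out


@dataclass
class CoreHaplotype:
    """Variants in the top-q fraction by |beta| of every supplied QTL."""

    variant_ids: list[str]
    q: float
    membership: pd.DataFrame  # universe x QTL boolean flags
    universe_size: int

    def __len__(self) -> int:
        return len(self.variant_ids)


def core_haplotype(summaries: list[QtlSummary], q: float = 0.05,
                   universe: set[str] | None = None) -> CoreHaplotype:
    """Intersect the per-QTL top-q sets (by absolute allele effect).

    Each summary contributes its top ``ceil(q * |universe|)`` variants ranked
    by |beta| (ties broken by smaller p, then variant id). The core haplotype
    is the intersection across all summaries; per-QTL membership flags are
    returned for every universe variant.
    """
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    if len(summaries) < 2:
        raise ValueError("need at least 2 QTL summaries")
    if universe is None:
        universe = set(summaries[0].tested()["id"])
        for s in summaries[1:]:
            universe &= set(s.tested()["id"])
    universe = set(universe)
    if not universe:
        raise ValueError("empty variant universe")
    k = int(np.ceil(q * len(universe)))
    flags = {}
    for s in summaries:
        t = s.tested()
        t = t[t["id"].isin(universe)].copy()
        missing = universe - set(t["id"])
        if missing:
            raise ValueError(f"universe variant(s) absent from {s.name!r}: "
                             f"{sorted(missing)[:3]}")
        t["_absbeta"] = t["beta"].abs()
        t = t.sort_values(["_absbeta", "p", "id"],
                          ascending=[False, True, True], kind="mergesort")
        flags[s.name or f"qtl{len(flags)}"] = set(t["id"].head(k))
    ids = sorted(universe)
    memb = pd.DataFrame({name: [v in top for v in ids] for name, top in flags.items()},
                        index=ids)
    core = sorted(set.intersection(*flags.values()))
    return CoreHaplotype(core, q, memb, len(universe))


def ld_r2(g: GenotypeMatrix, v1: str, v2: str) -> float:
    """Squared Pearson correlation of dosages at two variants.

    Computed over samples non-missing at both; undefined (error) for
    monomorphic variants.
    """
    d1 = g.dosage_of(v1)
    d2 = g.dosage_of(v2)
    ok = ~(np.isnan(d1) | np.isnan(d2))
    d1, d2 = d1[ok], d2[ok]
    if d1.std() == 0 or d2.std() == 0:
        raise ValueError("LD undefined: monomorphic variant")
    r = np.corrcoef(d1, d2)[0, 1]
    return float(r * r)


def variant_peak_overlap(variants: list[VariantRecord],
                         peaksets: list[PeakSet]) -> dict[str, list[tuple[str, str]]]:
    """Which peaks (assay, peak name) contain each variant.

    Containment uses 1-based inclusive intervals; a variant at a peak's
    start or end coordinate is contained. Returns a mapping from variant id
    to a list of ``(assay, peak_name)`` pairs (possibly empty).
    """
    trees: dict[str, IntervalTree] = {}
    for ps in peaksets:
        for p in ps.peaks:
            # IntervalTree is half-open; +1 makes [start, end] inclusive
            trees.setdefault(p.chrom, IntervalTree()).addi(
                p.start, p.end + 1, (ps.assay, p.name))
    out: dict[str, list[tuple[str, str]]] = {}
    for v in variants:
        hits = trees.get(v.chrom, IntervalTree())[v.pos]
        out[v.id] = sorted(iv.data for iv in hits)
    return out


def variant_density_percentile(positions, focus_window: tuple[int, int],
                               genome_window_counts, window_size: int) -> float:
    """Rank a focus window's variant density against a genome-wide distribution.

    ``positions`` are variant positions on the focus chromosome;
    ``genome_window_counts`` are per-window variant counts genome-wide for
    windows of ``window_size`` bases. The percentile is the fraction of
    genome windows with strictly lower density, times 100. Singleton
    exclusion is the caller's responsibility (pass filtered positions).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    counts = np.asarray(genome_window_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("genome_window_counts is empty")
    pos = np.asarray(positions)
    lo, hi = focus_window
    n_focus = int(np.sum((pos >= lo) & (pos <= hi)))
    focus_density = n_focus / window_size
    genome_density = counts / window_size
    return float(np.mean(genome_density < focus_density) * 100.0)


def coreg_table(results: list[CoregResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])
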