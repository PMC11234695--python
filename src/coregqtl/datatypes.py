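"""Core in-memory containers shared across the package.

Coordinate convention: all internal coordinates are 1-based inclusive
(``[start, end]`` covers ``end - start + 1`` bases). BED-family files use
0-based half-open coordinates and are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

PEAK_ASSAYS = ("H3K27ac", "H3K4Me1", "H3K4Me3", "ATAC")

#: Columns every QTL summary table carries, in canonical order.
QTL_SUMMARY_COLUMNS = ["id", "chrom", "pos", "ref", "alt", "maf", "n", "beta", "se", "p"]


@dataclass(frozen=True)
class VariantRecord:
    """A single bi-allelic variant.

    ``maf`` is the minor allele frequency, min(p, 1-p) of the alt-allele
    frequency; ``dr2`` is the imputation dosage R² carried through from the
    VCF INFO field (None when the source had none — it is data, never
    recomputed here).
    """

    id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    maf: float = float("nan")
    dr2: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.id}: ref equals alt ({self.ref})")


def maf_from_dosage(dosage: np.ndarray) -> float:
    """Minor allele frequency from a vector of alt-allele dosages in [0, 2].

    Missing entries (NaN) are ignored.
    """
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    p = float(d.mean() / 2.0)
    return min(p, 1.0 - p)


@dataclass
class GenotypeMatrix:
    """Samples × variants alt-allele dosage matrix with variant metadata.

    ``dosage[i, j]`` is the dosage of sample ``samples[i]`` at variant
    ``variants[j]``; values lie in [0, 2], NaN marks missing calls. Missing
    dosages are mean-imputed only at the point of use (GRM, association, LD),
    never persisted.
    """

    samples: list[str]
    variants: list[VariantRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (id, chrom, pos, ref, alt, maf, dr2)."""
        return pd.DataFrame(
            {
                "id": [v.id for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "maf": [v.maf for v in self.variants],
                "dr2": [v.dr2 for v in self.variants],
            }
        )

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(f"variant {variant_id!r} not present")

    def dosage_of(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_index(variant_id)]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        variants = [v for v, m in zip(self.variants, mask) if m]
        return GenotypeMatrix(list(self.samples), variants, self.dosage[:, mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), list(self.variants), self.dosage[idx, :])

    def recompute_maf(self) -> "GenotypeMatrix":
        """Return a copy whose stored MAFs are recomputed from the dosages."""
        variants = []
        for j, v in enumerate(self.variants):
            variants.append(
                VariantRecord(v.id, v.chrom, v.pos, v.ref, v.alt,
                              maf_from_dosage(self.dosage[:, j]), v.dr2)
            )
        return GenotypeMatrix(list(self.samples), variants, self.dosage.copy())


@dataclass(frozen=True)
class Peak:
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    score: float = 0.0
    signal_value: float = float("nan")
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"peak {self.name}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PeakSet:
    """Named genomic intervals from one peak-calling assay."""

    peaks: list[Peak]
    assay: str

    def __post_init__(self) -> None:
        if self.assay not in PEAK_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {PEAK_ASSAYS}")
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            raise ValueError("peak names must be unique within a PeakSet")

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, name: str) -> Peak:
        for p in self.peaks:
            if p.name == name:
                return p
        raise KeyError(name)

    def lengths(self) -> dict[str, int]:
        return {p.name: p.length for p in self.peaks}

    def in_window(self, chrom: str, start: int, end: int) -> "PeakSet":
        """Peaks fully inside ``chrom:[start, end]`` (1-based inclusive)."""
        kept = [p for p in self.peaks
                if p.chrom == chrom and p.start >= start and p.end <= end]
        return PeakSet(kept, self.assay)

    def mean_length(self) -> float:
        if not self.peaks:
            raise ValueError("empty PeakSet")
        return float(np.mean([p.length for p in self.peaks]))

    def coverage_fraction(self, chrom: str, start: int, end: int) -> float:
        """Fraction of window bases covered by at least one peak.

        Peaks are clipped to the window and overlaps merged before counting.
        """
        ivals = sorted((max(p.start, start), min(p.end, end))
                       for p in self.peaks
                       if p.chrom == chrom and p.end >= start and p.start <= end)
        covered = 0
        cur_s, cur_e = None, None
        for s, e in ivals:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    covered += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s + 1
        return covered / (end - start + 1)


@dataclass
class CountMatrix:
    """Peaks × samples non-negative read counts (ChIP/ATAC or matched input)."""

    peak_names: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_names), len(self.sample_ids)):
            raise ValueError(
                f"count shape {self.counts.shape} inconsistent with "
                f"{len(self.peak_names)} peaks x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.peak_names, columns=self.sample_ids)


class QtlSummary:
    """Per-variant association output: the currency between the association
    and co-regulation stages.

    Wraps a DataFrame with columns ``id, chrom, pos, ref, alt, maf, n, beta,
    se, p`` (one row per tested variant; monomorphic variants keep their row
    with NaN beta/se/p and ``status`` = "monomorphic").
    """

    def __init__(self, table: pd.DataFrame, name: str = "") -> None:
        missing = [c for c in QTL_SUMMARY_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"QtlSummary table missing columns: {missing}")
        self.table = table.reset_index(drop=True)
        self.name = name

    def __len__(self) -> int:
        return len(self.table)

    def tested(self) -> pd.DataFrame:
        """Rows with a defined test result (finite beta, se, p)."""
        t = self.table
        ok = np.isfinite(t["beta"]) & np.isfinite(t["se"]) & np.isfinite(t["p"])
        return t[ok]

    def top_variant(self) -> pd.Series:
        t = self.tested()
        if t.empty:
            raise ValueError("no tested variants")
        return t.loc[t["p"].idxmin()]

    def in_window(self, chrom: str, start: int, end: int) -> "QtlSummary":
        t = self.table
        keep = (t["chrom"].astype(str) == str(chrom)) & (t["pos"] >= start) & (t["pos"] <= end)
        return QtlSummary(t[keep].copy(), name=self.name)
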