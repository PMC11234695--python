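"""Readers and writers for the external formats the pipeline exchanges.

Every other module is format-agnostic: it works on the containers defined in
:mod:`coregqtl.datatypes`, and this module owns the conversion between file
coordinates (BED-family 0-based half-open) and the internal 1-based inclusive
convention.
"""

from __future__ import annotations

import io as _io
import os
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .datatypes import (
    QTL_SUMMARY_COLUMNS,
    CountMatrix,
    GenotypeMatrix,
    Peak,
    PeakSet,
    QtlSummary,
    VariantRecord,
    maf_from_dosage,
)


class FormatError(ValueError):
    """A file did not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, region: tuple[str, int, int] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    The DS (dosage) FORMAT field is used when present, otherwise GT is
    converted to an alt-allele count. Missing calls become NaN. MAF is
    recomputed from the non-missing dosages; DR2 is taken from INFO when
    present. ``region`` is ``(chrom, start, end)`` in 1-based inclusive
    coordinates; a region containing no variants yields an empty matrix.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise FormatError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if region is not None:
            chrom, start, end = region
            if var.CHROM != str(chrom) or not (start <= var.POS <= end):
                continue
        alt = var.ALT[0] if var.ALT else "."
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ds = var.format("DS")
        if ds is not None:
            dos = np.asarray(ds, dtype=float).reshape(-1)
            dos = np.where((dos < 0) | (dos > 2), np.nan, dos)
        else:
            # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            gt = np.asarray(var.gt_types)
            dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        dr2 = var.INFO.get("DR2")
        if dr2 is not None:
            dr2 = float(dr2)
        variants.append(
            VariantRecord(vid, var.CHROM, var.POS, var.REF, alt,
                          maf=maf_from_dosage(dos), dr2=dr2)
        )
        rows.append(dos)
    vcf.close()
    dosage = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosage)


def write_vcf(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a GenotypeMatrix as a VCF 4.2 file carrying DS dosages.

    Hard-call GT is emitted alongside DS (rounded dosage) so that GT-only
    consumers still work; DR2 goes to INFO when the variant has one.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Dosage R-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        for chrom in dict.fromkeys(v.chrom for v in g.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        for j, v in enumerate(g.variants):
            info = f"DR2={v.dr2:.6g}" if v.dr2 is not None else "."
            cells = []
            for d in g.dosage[:, j]:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(hard, 0), 2)]
                    cells.append(f"{gt}:{d:.6g}")
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT:DS\t"
                     + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Peaks (BED / narrowPeak / broadPeak)
# ---------------------------------------------------------------------------

_DIALECT_COLS = {"narrowPeak": 10, "broadPeak": 9, "bed": 3}


def read_peaks(path: str | os.PathLike, dialect: str, assay: str = "ATAC") -> PeakSet:
    """Read a BED-family peak file into a :class:`PeakSet`.

    narrowPeak has 10 columns, broadPeak 9, plain BED at least 3. File
    coordinates (0-based half-open) are converted to internal 1-based
    inclusive. Absent names are autogenerated as ``<assay>-<index>``.
    """
    if dialect not in _DIALECT_COLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    peaks: list[Peak] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            need = _DIALECT_COLS[dialect]
            if dialect in ("narrowPeak", "broadPeak") and len(parts) != need:
                raise FormatError(
                    f"{path}:{i + 1}: {dialect} requires {need} columns, found {len(parts)}")
            if dialect == "bed" and len(parts) < need:
                raise FormatError(f"{path}:{i + 1}: BED requires >= 3 columns")
            chrom = parts[0]
            start0, end0 = int(parts[1]), int(parts[2])
            start, end = start0 + 1, end0  # half-open -> 1-based inclusive
            if start > end:
                raise FormatError(f"{path}:{i + 1}: empty or inverted interval")
            name = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else f"{assay}-{i}"
            score = float(parts[4]) if len(parts) > 4 else 0.0
            signal = float(parts[6]) if len(parts) > 6 else float("nan")
            qval = float(parts[8]) if len(parts) > 8 else float("nan")
            peaks.append(Peak(name, chrom, start, end, score, signal, qval))
    return PeakSet(peaks, assay)


def write_peaks(ps: PeakSet, path: str | os.PathLike, dialect: str = "narrowPeak") -> None:
    """Write a PeakSet back to BED-family coordinates (0-based half-open)."""
    with open(path, "w") as fh:
        for p in ps.peaks:
            start0, end0 = p.start - 1, p.end
            if dialect == "bed":
                fh.write(f"{p.chrom}\t{start0}\t{end0}\t{p.name}\t{p.score:g}\t.\n")
            elif dialect == "broadPeak":
                fh.write(f"{p.chrom}\t{start0}\t{end0}\t{p.name}\t{p.score:g}\t.\t"
                         f"{p.signal_value:g}\t-1\t{p.q_value:g}\n")
            elif dialect == "narrowPeak":
                fh.write(f"{p.chrom}\t{start0}\t{end0}\t{p.name}\t{p.score:g}\t.\t"
                         f"{p.signal_value:g}\t-1\t{p.q_value:g}\t-1\n")
            else:
                raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Count matrices / phenotype tables (TSV)
# ---------------------------------------------------------------------------

def read_count_matrix(path: str | os.PathLike) -> CountMatrix:
    """TSV with the peak name in the first column and sample ids as header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       df.to_numpy())


def write_count_matrix(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="peak")


def read_phenotype_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotype_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QTL summaries (TSV)
# ---------------------------------------------------------------------------

def read_qtl_summary(path: str | os.PathLike, name: str = "") -> QtlSummary:
    df = pd.read_csv(path, sep="\t")
    return QtlSummary(df, name=name or Path(path).stem)


def write_qtl_summary(qs: QtlSummary, path: str | os.PathLike) -> None:
    cols = QTL_SUMMARY_COLUMNS + [c for c in qs.table.columns if c not in QTL_SUMMARY_COLUMNS]
    qs.table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# JASPAR PFMs
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: str | os.PathLike) -> list[motifs.Motif]:
    """Parse a JASPAR-format PFM file (">ID NAME" header, bracketed A/C/G/T rows).

    Returns Bio.motifs Motif objects; counts are validated to be non-negative
    and rectangular.
    """
    with open(path) as fh:
        try:
            records = motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"cannot parse JASPAR PFM file {path}: {exc}") from exc
    out = list(records)
    for m in out:
        widths = {len(m.counts[b]) for b in "ACGT"}
        if len(widths) != 1:
            raise FormatError(f"motif {m.matrix_id}: count rows of unequal length")
        for b in "ACGT":
            if any(c < 0 for c in m.counts[b]):
                raise FormatError(f"motif {m.matrix_id}: negative count")
    return out


def write_jaspar_pfm(pfms: list[motifs.Motif], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for m in pfms:
            fh.write(motifs.write([m], "jaspar"))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# Variant filtering (MAF / DR2)
# ---------------------------------------------------------------------------

def filter_variants(g: GenotypeMatrix, maf_min: float = 0.005,
                    dr2_min: float = 0.9) -> GenotypeMatrix:
    """Keep variants with ``maf > maf_min`` and (no DR2 or ``dr2 > dr2_min``).

    Both inequalities are strict; a variant at exactly the threshold is
    removed. Variants lacking a DR2 annotation pass the DR2 rule.
    """
    if not (0 <= maf_min <= 1 and 0 <= dr2_min <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    mask = np.array(
        [(v.maf > maf_min) and (v.dr2 is None or v.dr2 > dr2_min) for v in g.variants],
        dtype=bool,
    )
    return g.subset_variants(mask)
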