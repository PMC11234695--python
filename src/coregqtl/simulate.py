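"""Synthetic data with the causal structure the analysis assumes.

The generator emulates an F2 cross between two founder breeds: LD-blocked
genotypes built from two haplotype pools with divergent allele frequencies, a
high-frequency core haplotype of tightly linked variants around a single
causal variant, and a molecular cascade in which the causal dosage raises the
log-mean of targeted chromatin peaks, the log expression of a target gene,
and (on the natural-log scale) a repeated-measures protein concentration with
a polygenic animal effect of specified heritability. Everything downstream —
phenotype construction, association, co-regulation, TFBS scanning — is
testable against this planted truth without any external data.

All randomness flows from the single config seed; equal configs give
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (CountMatrix, GenotypeMatrix, Peak, PeakSet,
                        VariantRecord, maf_from_dosage)

#: Region emulated: a ~2 Mb window on one autosome.
REGION_CHROM = "22"
REGION_START = 51_946_110
REGION_END = 53_986_647


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults follow the emulated study design: an F2 population of several
    hundred animals, a common causal haplotype (MAF about 0.45) of tightly
    linked variants, a per-allele protein effect of 0.56 natural-log units,
    and log-scale heritability around 0.4.
    """

    n_animals: int = 650
    n_variants: int = 2000
    n_background_variants: int = 1000
    background_chrom: str = "1"
    n_peaks: int = 60
    n_genes: int = 200
    ld_block_size: int = 50
    n_flank_linked: int = 2
    core_haplotype_size: int = 20
    core_haplotype_r2_min: float = 0.99
    causal_maf: float = 0.45
    pool_divergence: float = 0.2
    alpha_chromatin: float = 0.5
    alpha_expression: float = 0.5
    alpha_protein: float = 0.56
    h2_protein: float = 0.4
    sigma2_pe: float = 0.05
    sigma2_residual: float = 0.35
    period_means: tuple = (4.2, 5.2, 5.1)  # ln mg/L for peak, mid, late
    record_prob: float = 0.9
    mean_depth_chip: float = 200.0
    mean_depth_input: float = 100.0
    mean_depth_expr: float = 500.0
    nb_dispersion: float = 10.0
    depth_sd_log: float = 0.3
    n_target_peaks: int = 2
    n_periods: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_haplotype_size > self.n_variants:
            raise ValueError("core_haplotype_size exceeds n_variants")
        if not (0 < self.causal_maf <= 0.5):
            raise ValueError("causal_maf must lie in (0, 0.5]")
        if not (0 < self.core_haplotype_r2_min <= 1):
            raise ValueError("core_haplotype_r2_min must lie in (0, 1]")
        if not (0 <= self.h2_protein < 1):
            raise ValueError("h2_protein must lie in [0, 1)")
        for name in ("n_animals", "n_variants", "n_peaks", "ld_block_size",
                     "n_periods"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Planted ground truth for a simulated data set."""

    causal_variant_ids: list[str]
    core_haplotype_ids: list[str]
    alpha_chromatin: float
    alpha_expression: float
    alpha_protein: float
    h2_protein: float
    seed: int
    target_peaks: list[str] = field(default_factory=list)
    target_gene: str = "gene_target"

    def __post_init__(self) -> None:
        if not set(self.causal_variant_ids) <= set(self.core_haplotype_ids):
            raise ValueError("causal variants must belong to the core haplotype")


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """F2 haplotype-pool genotypes with LD blocks and a planted core haplotype.

    Two founder pools have blockwise-divergent allele frequencies; each
    animal receives two recombined gametes (pool membership redrawn per
    block). Within a block, each variant copies the block's latent state with
    a flip probability that grows with distance from the block anchor, so LD
    decays along the block. The core haplotype is ``core_haplotype_size``
    consecutive variants around the causal variant whose pairwise dosage R2
    is at least ``core_haplotype_r2_min`` (enforced by construction).
    """
    rng_geno, rng_core = _rngs(cfg.seed, 6)[:2]
    n, m = cfg.n_animals, cfg.n_variants
    n_gam = 2 * n
    spacing = (REGION_END - REGION_START) // (m + 1)
    positions = REGION_START + spacing * (1 + np.arange(m))

    block_ids = np.arange(m) // cfg.ld_block_size
    n_blocks = int(block_ids.max()) + 1
    # blockwise divergent pool frequencies
    base = rng_geno.uniform(0.15, 0.85, size=n_blocks)
    div = cfg.pool_divergence
    p_pool = np.stack([np.clip(base - div, 0.02, 0.98),
                       np.clip(base + div, 0.02, 0.98)])  # 2 x blocks
    frac = (np.arange(m) % cfg.ld_block_size) / max(cfg.ld_block_size - 1, 1)
    eps = 0.45 * (1.0 - np.exp(-2.0 * frac))  # flip prob grows along the block

    gam = np.empty((n_gam, m), dtype=np.int8)
    for blk in range(n_blocks):
        cols = np.where(block_ids == blk)[0]
        pool = rng_geno.integers(0, 2, size=n_gam)
        state = (rng_geno.random(n_gam) < p_pool[pool, blk]).astype(np.int8)
        flips = rng_geno.random((n_gam, cols.size)) < eps[cols]
        gam[:, cols] = state[:, None] ^ flips.astype(np.int8)

    # causal variant: centre of the region, frequency around causal_maf
    causal_idx = m // 2
    core_lo = causal_idx - cfg.core_haplotype_size // 2
    core_lo = max(0, min(core_lo, m - cfg.core_haplotype_size))
    core_idx = np.arange(core_lo, core_lo + cfg.core_haplotype_size)
    p_hi = min(0.95, cfg.causal_maf + div)
    p_lo = max(0.05, cfg.causal_maf - div)
    pool_c = rng_core.integers(0, 2, size=n_gam)
    causal_gam = (rng_core.random(n_gam) <
                  np.where(pool_c == 1, p_hi, p_lo)).astype(np.int8)
    gam[:, causal_idx] = causal_gam
    causal_dos = (causal_gam[0::2] + causal_gam[1::2]).astype(float)
    # near-perfect LD vs the causal variant guarantees the pairwise floor;
    # flips are reverted one by one if sampling noise pushes R2 below it
    target = np.sqrt(cfg.core_haplotype_r2_min)
    for j in core_idx:
        if j == causal_idx:
            continue
        k = 1 + int(rng_core.integers(0, 2))  # 1 or 2 flipped gametes
        flips = list(rng_core.choice(n_gam, size=k, replace=False))
        col = causal_gam.copy()
        for f in flips:
            col[f] ^= 1
        while flips and _dosage_r2((col[0::2] + col[1::2]).astype(float),
                                   causal_dos) < target:
            col[flips.pop()] ^= 1
        gam[:, j] = col

    # a small flank on each side of the core is partially linked to the
    # causal gamete, giving the region a realistic LD shoulder
    flank = [j for j in range(core_idx[0] - cfg.n_flank_linked, core_idx[0])
             if j >= 0]
    flank += [j for j in range(core_idx[-1] + 1,
                               core_idx[-1] + 1 + cfg.n_flank_linked)
              if j < m]
    for j in flank:
        e = rng_core.uniform(0.25, 0.45)
        flips = (rng_core.random(n_gam) < e).astype(np.int8)
        gam[:, j] = causal_gam ^ flips

    dosage = (gam[0::2] + gam[1::2]).astype(float)

    # final guarantee: any core pair still under the floor collapses to a copy
    for j in core_idx:
        if j != causal_idx and any(
                _dosage_r2(dosage[:, j], dosage[:, jj]) < cfg.core_haplotype_r2_min
                for jj in core_idx if jj != j):
            dosage[:, j] = causal_dos

    samples = [f"animal{i:04d}" for i in range(n)]
    variants = []
    for j in range(m):
        variants.append(VariantRecord(
            id=f"rs{1_000_000 + j}", chrom=REGION_CHROM, pos=int(positions[j]),
            ref="A", alt="G", maf=maf_from_dosage(dosage[:, j]), dr2=None))

    # unlinked background variants on another chromosome: the substrate for
    # the genome-wide GRM / polygenic effect in a LOCO design
    mb = cfg.n_background_variants
    if mb:
        freqs = rng_geno.uniform(0.1, 0.9, size=mb)
        bg_gam = (rng_geno.random((n_gam, mb)) < freqs).astype(np.int8)
        bg_dos = (bg_gam[0::2] + bg_gam[1::2]).astype(float)
        for j in range(mb):
            variants.append(VariantRecord(
                id=f"bg{j}", chrom=cfg.background_chrom, pos=1 + 1000 * j,
                ref="A", alt="G", maf=maf_from_dosage(bg_dos[:, j]), dr2=None))
        dosage = np.column_stack([dosage, bg_dos])

    g = GenotypeMatrix(samples, variants, dosage)
    truth = SimTruth(
        causal_variant_ids=[variants[causal_idx].id],
        core_haplotype_ids=[variants[j].id for j in core_idx],
        alpha_chromatin=cfg.alpha_chromatin,
        alpha_expression=cfg.alpha_expression,
        alpha_protein=cfg.alpha_protein,
        h2_protein=cfg.h2_protein,
        seed=cfg.seed)
    return g, truth


def polygenic_effect(dosage: np.ndarray, variance: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Additive polygenic values with the covariance of the realized GRM.

    Draws ``a ~ N(0, variance * G)`` where G is the VanRaden GRM of the
    supplied dosages, via the eigendecomposition of G.
    """
    if variance <= 0:
        return np.zeros(dosage.shape[0])
    d = np.array(dosage, dtype=float)
    p = d.mean(axis=0) / 2.0
    ok = (p > 0) & (p < 1)
    z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
    G = z @ z.T / ok.sum()
    w, U = np.linalg.eigh(G)
    w = np.clip(w, 0, None)
    return U @ (np.sqrt(w * variance) * rng.standard_normal(w.size))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, r: float) -> np.ndarray:
    """Negative binomial with mean mu and dispersion r (var = mu + mu^2/r)."""
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


@dataclass
class CascadeData:
    """Molecular layers simulated downstream of the genotypes."""

    peaks: PeakSet
    chip: CountMatrix
    chip_input: CountMatrix
    expression: pd.DataFrame      # genes x samples counts
    protein: pd.DataFrame         # animal_id, period, value
    target_peaks: list[str]
    target_gene: str


def simulate_molecular_cascade(g: GenotypeMatrix, truth: SimTruth,
                               cfg: SimConfig) -> CascadeData:
    """Chromatin counts, expression counts and protein records driven by the
    causal dosage.

    ChIP counts are negative binomial with a log-mean combining a baseline,
    a peak-length term, a per-sample depth term, and (for target peaks)
    ``alpha_chromatin * dosage``; input counts share the depth structure but
    carry no genetic effect. Expression of the target gene carries
    ``alpha_expression * dosage``. Protein concentration for animal i in
    period t is ``exp(mu_t + alpha_protein * dosage_i + a_i + pe_i + e_it)``
    with polygenic ``a`` giving heritability ``h2_protein`` on the log scale
    and period means ordered peak < late < mid.
    """
    for vid in truth.causal_variant_ids:
        g.variant_index(vid)  # KeyError if absent
    rng_peak, rng_chip, rng_expr, rng_prot = _rngs(cfg.seed + 1, 4)
    n = g.n_samples
    dose = g.dosage_of(truth.causal_variant_ids[0])
    dose_c = dose - dose.mean()

    # --- peaks tiling the region; targets placed over the core haplotype ---
    causal_pos = next(v.pos for v in g.variants if v.id == truth.causal_variant_ids[0])
    lengths = rng_peak.integers(300, 2000, size=cfg.n_peaks)
    span = REGION_END - REGION_START
    starts = np.sort(rng_peak.integers(REGION_START, REGION_END - 2000,
                                       size=cfg.n_peaks))
    peaks = []
    target_names = []
    for i in range(cfg.n_peaks):
        name = f"ATAC-{i}"
        start, length = int(starts[i]), int(lengths[i])
        if i < cfg.n_target_peaks:
            # overlap the causal variant
            start = causal_pos - 200 - 700 * i
            length = 1500
            target_names.append(name)
        peaks.append(Peak(name, REGION_CHROM, start, start + length - 1,
                          score=float(rng_peak.integers(50, 3000)),
                          signal_value=float(rng_peak.uniform(5, 40)),
                          q_value=float(rng_peak.uniform(5, 900))))
    peakset = PeakSet(peaks, "ATAC")

    # --- ChIP / input counts -------------------------------------------------
    depth = np.exp(rng_chip.normal(0.0, cfg.depth_sd_log, size=n))
    depth_in = np.exp(rng_chip.normal(0.0, cfg.depth_sd_log, size=n))
    base = rng_chip.uniform(-0.5, 0.5, size=cfg.n_peaks)
    lenterm = np.log(np.array([p.length for p in peaks]) / 1000.0)
    logmu = (np.log(cfg.mean_depth_chip) + base[:, None] + lenterm[:, None]
             + np.log(depth)[None, :])
    for t, name in enumerate(target_names):
        i = [p.name for p in peaks].index(name)
        logmu[i] += truth.alpha_chromatin * dose_c
    chip = _nb_draw(rng_chip, np.exp(logmu), cfg.nb_dispersion)
    logmu_in = (np.log(cfg.mean_depth_input) + base[:, None] + lenterm[:, None]
                + np.log(depth_in)[None, :])
    chip_in = _nb_draw(rng_chip, np.exp(logmu_in), cfg.nb_dispersion)
    names = [p.name for p in peaks]
    chip_cm = CountMatrix(names, list(g.samples), chip)
    input_cm = CountMatrix(names, list(g.samples), chip_in)

    # --- expression ----------------------------------------------------------
    depth_e = np.exp(rng_expr.normal(0.0, cfg.depth_sd_log, size=n))
    gene_base = rng_expr.uniform(-1.0, 2.0, size=cfg.n_genes)
    logmu_e = (np.log(cfg.mean_depth_expr) + gene_base[:, None]
               + np.log(depth_e)[None, :])
    logmu_e[0] += truth.alpha_expression * dose_c
    expr = _nb_draw(rng_expr, np.exp(logmu_e), cfg.nb_dispersion)
    gene_names = [truth.target_gene] + [f"gene_{i}" for i in range(1, cfg.n_genes)]
    expression = pd.DataFrame(expr, index=gene_names, columns=g.samples)

    # --- protein repeated measures ------------------------------------------
    h2 = truth.h2_protein
    env = cfg.sigma2_pe + cfg.sigma2_residual
    var_a = h2 * env / (1.0 - h2) if h2 > 0 else 0.0
    # the polygenic background stands for the rest of the genome: drawn from
    # the background-chromosome GRM (the causal effect enters only through
    # alpha_protein * dosage)
    away = np.array([v.chrom != REGION_CHROM for v in g.variants])
    if not away.any():
        away = np.array([abs(v.pos - causal_pos) > 100_000 for v in g.variants])
    a = polygenic_effect(g.dosage[:, away], var_a, rng_prot)
    pe = rng_prot.normal(0.0, np.sqrt(cfg.sigma2_pe), size=n)
    period_names = ["peak", "mid", "late"][: cfg.n_periods]
    mu = list(cfg.period_means)[: cfg.n_periods]
    present = rng_prot.random((n, cfg.n_periods)) < cfg.record_prob
    none = ~present.any(axis=1)
    present[none, 0] = True  # every animal keeps at least one record
    rows = []
    for t, period in enumerate(period_names):
        e = rng_prot.normal(0.0, np.sqrt(cfg.sigma2_residual), size=n)
        logval = mu[t] + truth.alpha_protein * dose + a + pe + e
        for i in range(n):
            if present[i, t]:
                rows.append((g.samples[i], period, float(np.exp(logval[i]))))
    protein = pd.DataFrame(rows, columns=["animal_id", "period", "value"])
    return CascadeData(peakset, chip_cm, input_cm, expression, protein,
                       target_names, truth.target_gene)


def plant_motif(seq_len: int, pwm, offset: int, variant_offset: int,
                seed: int = 0) -> tuple[str, VariantRecord]:
    """Background sequence with the PWM consensus planted, plus a disrupting
    variant.

    The background is i.i.d. from the PWM background distribution; the
    consensus word is written at ``offset`` (0-based); the returned variant
    sits at ``variant_offset`` within the motif, its ref allele being the
    consensus base and its alt the base minimising that column's score.
    """
    if offset + pwm.width > seq_len:
        raise ValueError("motif does not fit: offset + width > seq_len")
    if not (0 <= variant_offset < pwm.width):
        raise ValueError("variant_offset must fall within the motif")
    rng = np.random.Generator(np.random.PCG64(seed))
    from .tfbs import BASES
    bases = np.array(list(BASES))
    seq = rng.choice(bases, size=seq_len, p=pwm.background)
    consensus = pwm.consensus()
    seq[offset: offset + pwm.width] = list(consensus)
    col = pwm.scores[:, variant_offset]
    ref = consensus[variant_offset]
    alt = BASES[int(np.argmin(col))]
    if alt == ref:  # flat column: any other base
        alt = next(b for b in BASES if b != ref)
    var = VariantRecord(id=f"sim_var_{offset + variant_offset}", chrom="seq",
                        pos=offset + variant_offset + 1, ref=ref, alt=alt)
    return "".join(seq), var


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

#: A small synthetic STAT-like palindromic PFM (TTCnnnGAA core) used for the
#: bundled motif fixture; counts are invented for testing, not a database entry.
SYNTHETIC_STAT_PFM = np.array([
    #  T   T   C   T   G   G   G   A   A
    [2,  1,  0, 20,  5,  2,  0, 90, 88],   # A
    [3,  2, 95, 25,  5,  3,  2,  4,  5],   # C
    [2,  2,  2, 25, 80, 90, 95,  3,  4],   # G
    [93, 95,  3, 30, 10,  5,  3,  3,  3],  # T
], dtype=float)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(outdir, cfg: SimConfig) -> dict:
    """Simulate everything and write it in the formats the readers consume.

    Emits VCF, narrowPeak, ChIP/input/expression/protein TSVs, a JASPAR PFM,
    FASTA with a planted disrupted motif, and a truth JSON; returns a
    manifest mapping each file name to its sha256 checksum.
    """
    from . import io as cio
    from .tfbs import pfm_to_pwm

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g, truth = simulate_genotypes(cfg)
    cascade = simulate_molecular_cascade(g, truth, cfg)
    truth.target_peaks = cascade.target_peaks

    cio.write_vcf(g, out / "genotypes.vcf")
    cio.write_peaks(cascade.peaks, out / "peaks.narrowPeak", "narrowPeak")
    cio.write_count_matrix(cascade.chip, out / "chip_counts.tsv")
    cio.write_count_matrix(cascade.chip_input, out / "input_counts.tsv")
    cascade.expression.to_csv(out / "expression_counts.tsv", sep="\t",
                              index_label="gene")
    cio.write_phenotype_table(cascade.protein, out / "protein.tsv")

    pwm = pfm_to_pwm(SYNTHETIC_STAT_PFM)
    pwm.tf_id, pwm.tf_name = "SYN0001", "SYNSTAT"
    seq, var = plant_motif(400, pwm, offset=180, variant_offset=4,
                           seed=cfg.seed + 17)
    cio.write_fasta({"peak_seq": seq}, out / "peak_sequence.fasta")
    with open(out / "motif.pfm", "w") as fh:
        fh.write(">SYN0001 SYNSTAT\n")
        for b, row in zip("ACGT", SYNTHETIC_STAT_PFM):
            fh.write(f"{b} [ " + " ".join(str(int(c)) for c in row) + " ]\n")
    truth_doc = asdict(truth)
    truth_doc["motif_variant"] = {"id": var.id, "pos": var.pos,
                                  "ref": var.ref, "alt": var.alt}
    truth_doc["config"] = asdict(cfg)
    (out / "truth.json").write_text(json.dumps(truth_doc, indent=2) + "\n")

    files = ["genotypes.vcf", "peaks.narrowPeak", "chip_counts.tsv",
             "input_counts.tsv", "expression_counts.tsv", "protein.tsv",
             "peak_sequence.fasta", "motif.pfm", "truth.json"]
    manifest = {f: _sha256(out / f) for f in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
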