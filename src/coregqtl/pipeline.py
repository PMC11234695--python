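"""End-to-end orchestration: staged runs with provenance, and a one-command
synthetic demonstration of the full causal chain.

The demo simulates an F2 population with a planted causal haplotype, builds
the protein / expression / chromatin phenotypes, runs mixed-model association
for all four QTL layers against a leave-one-chromosome-out GRM, measures
co-regulation (correlations, pseudo-R2, core haplotype vs truth), repeats the
protein scan conditional on the causal variant, and scores the planted
binding-site disruption.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import chromatin as chrom
from . import coreg
from . import io as cio
from . import protein as prot
from . import simulate as sim
from . import tfbs
from .datatypes import GenotypeMatrix, QtlSummary, VariantRecord

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Run-wide paths and thresholds (YAML-serialisable)."""

    workdir: str = "coregqtl_run"
    window: str = f"{sim.REGION_CHROM}:{sim.REGION_START}-{sim.REGION_END}"
    corr_window_kb: float = 100.0      # half-width around the causal position
    q_core: float = 0.05
    alpha: float = 0.05
    maf_min: float = 0.005
    dr2_min: float = 0.9
    rel_score: float = 0.9
    tfm_p: float = 1e-5
    pca_sds: float = 4.0
    pca_npcs_chromatin: int = 7
    pca_npcs_expression: int = 6
    seed: int = 0
    sim: dict = field(default_factory=dict)

    def sim_config(self) -> sim.SimConfig:
        return sim.SimConfig(seed=self.seed, **self.sim)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()

    def parse_window(self) -> tuple[str, int, int]:
        chrom_, rest = self.window.split(":")
        start, end = rest.split("-")
        return chrom_, int(start), int(end)


# ---------------------------------------------------------------------------
# Staged execution with provenance
# ---------------------------------------------------------------------------

STAGE_DEPS = {
    "simulate": [],
    "pheno": ["simulate"],
    "chrompheno": ["simulate"],
    "assoc": ["simulate", "pheno", "chrompheno"],
    "coreg": ["assoc"],
    "tfbs": ["simulate", "assoc"],
}


class StageDependencyError(RuntimeError):
    pass


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _provenance_path(workdir: Path, stage: str) -> Path:
    return workdir / "provenance" / f"{stage}.json"


def _write_provenance(workdir: Path, stage: str, cfg: PipelineConfig,
                      inputs: list[Path], outputs: list[Path]) -> None:
    doc = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "inputs": {p.name: _sha256_file(p) for p in inputs},
        "outputs": {p.name: _sha256_file(p) for p in outputs},
    }
    path = _provenance_path(workdir, stage)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _up_to_date(workdir: Path, stage: str, cfg: PipelineConfig,
                inputs: list[Path]) -> bool:
    path = _provenance_path(workdir, stage)
    if not path.exists():
        return False
    doc = json.loads(path.read_text())
    if doc.get("config_hash") != cfg.config_hash():
        return False
    for p in inputs:
        if not p.exists() or doc["inputs"].get(p.name) != _sha256_file(p):
            return False
    for name in doc.get("outputs", {}):
        if not any((workdir / sub / name).exists()
                   for sub in ("data", "pheno", "chrompheno", "assoc",
                               "coreg", "tfbs", ".")):
            return False
    return True


def run_stage(stage: str, cfg: PipelineConfig, force: bool = False) -> list[Path]:
    """Run one pipeline stage, writing outputs plus a provenance sidecar.

    Rerunning with unchanged inputs and config is a no-op unless ``force``.
    Raises :class:`StageDependencyError` naming the missing prerequisite.
    """
    if stage not in STAGE_DEPS:
        raise ValueError(f"unknown stage {stage!r}; known: {sorted(STAGE_DEPS)}")
    workdir = Path(cfg.workdir)
    for dep in STAGE_DEPS[stage]:
        if not _provenance_path(workdir, dep).exists():
            raise StageDependencyError(
                f"stage {stage!r} requires stage {dep!r} to have run first")
    fn = globals()[f"_stage_{stage}"]
    inputs = fn(cfg, dry=True)
    if not force and _up_to_date(workdir, stage, cfg, inputs):
        return []
    outputs = fn(cfg, dry=False)
    _write_provenance(workdir, stage, cfg, inputs, outputs)
    return outputs


def _data_dir(cfg: PipelineConfig) -> Path:
    return Path(cfg.workdir) / "data"


def _stage_simulate(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    out = _data_dir(cfg)
    if dry:
        return []
    sim.write_fixture_bundle(out, cfg.sim_config())
    return sorted(out.iterdir())


def _load_genotypes(cfg: PipelineConfig) -> GenotypeMatrix:
    g = cio.read_vcf(_data_dir(cfg) / "genotypes.vcf")
    return cio.filter_variants(g, cfg.maf_min, cfg.dr2_min)


def _stage_pheno(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    d = _data_dir(cfg)
    inputs = [d / "protein.tsv", d / "genotypes.vcf"]
    if dry:
        return inputs
    out = Path(cfg.workdir) / "pheno"
    out.mkdir(parents=True, exist_ok=True)
    tbl = cio.read_phenotype_table(d / "protein.tsv")
    g = _load_genotypes(cfg)
    grm = assoc.compute_grm(g)
    A = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    res = prot.RepeatedMeasuresModel(tbl, A).fit()
    cio.write_phenotype_table(res.aggregate, out / "aggregate.tsv")
    logs = prot.prepare_log_phenotypes(tbl)
    for period, series in logs.items():
        series.rename_axis("animal_id").reset_index(name="value").to_csv(
            out / f"log_{period}.tsv", sep="\t", index=False)
    vc = {"sigma2_additive": res.sigma2_additive, "sigma2_pe": res.sigma2_pe,
          "sigma2_residual": res.sigma2_residual, "h2": res.h2,
          "se_h2": res.se_h2, "lrt_p": res.lrt_p}
    (out / "variance_components.json").write_text(json.dumps(vc, indent=2) + "\n")
    return sorted(out.iterdir())


def _stage_chrompheno(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    d = _data_dir(cfg)
    inputs = [d / "chip_counts.tsv", d / "input_counts.tsv",
              d / "peaks.narrowPeak", d / "expression_counts.tsv"]
    if dry:
        return inputs
    out = Path(cfg.workdir) / "chrompheno"
    out.mkdir(parents=True, exist_ok=True)
    cm = cio.read_count_matrix(d / "chip_counts.tsv")
    im = cio.read_count_matrix(d / "input_counts.tsv")
    peaks = cio.read_peaks(d / "peaks.narrowPeak", "narrowPeak")
    kept = chrom.filter_peaks(cm, im, peaks)
    idx = [cm.peak_names.index(p) for p in kept]
    cm_f = type(cm)(kept, cm.sample_ids, cm.counts[idx])
    im_f = type(im)(kept, im.sample_ids, im.counts[idx])
    pheno = chrom.chromatin_phenotypes(cm_f, im_f)
    excluded = chrom.pca_outliers(pheno.residuals.T, cfg.pca_npcs_chromatin,
                                  cfg.pca_sds, pheno.sample_ids)
    pheno.to_frame().to_csv(out / "chromatin_phenotypes.tsv", sep="\t",
                            index_label="peak")
    (out / "excluded_samples.txt").write_text("\n".join(map(str, excluded)) + "\n")
    expr = pd.read_csv(d / "expression_counts.tsv", sep="\t", index_col=0)
    norm, _ = chrom.expression_normalize(expr.to_numpy())
    expr_excl = chrom.pca_outliers(norm.T, min(cfg.pca_npcs_expression,
                                               norm.shape[0] - 1, norm.shape[1] - 1),
                                   cfg.pca_sds, list(expr.columns))
    target = pd.DataFrame({"animal_id": expr.columns, "value": norm[0]})
    cio.write_phenotype_table(target, out / "expression_phenotype.tsv")
    (out / "expression_excluded.txt").write_text("\n".join(map(str, expr_excl)) + "\n")
    return sorted(out.iterdir())


def _loco_grm(cfg: PipelineConfig, g: GenotypeMatrix) -> assoc.Grm:
    """Leave-one-chromosome-out GRM: built from everything off the scan
    chromosome (falls back to a leave-one-segment-out window when the data
    has a single chromosome)."""
    chrom_, start, end = cfg.parse_window()
    if any(v.chrom != chrom_ for v in g.variants):
        return assoc.compute_grm(g, exclude=chrom_)
    truth = json.loads((_data_dir(cfg) / "truth.json").read_text())
    causal = truth["causal_variant_ids"][0]
    pos = next(v.pos for v in g.variants if v.id == causal)
    half = int(cfg.corr_window_kb * 1000)
    return assoc.compute_grm(g, exclude=(chrom_, pos - half, pos + half))


def _stage_assoc(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    d = _data_dir(cfg)
    w = Path(cfg.workdir)
    inputs = [d / "genotypes.vcf", w / "pheno" / "log_peak.tsv",
              w / "chrompheno" / "chromatin_phenotypes.tsv",
              w / "chrompheno" / "expression_phenotype.tsv"]
    if dry:
        return inputs
    out = w / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    g_all = _load_genotypes(cfg)
    grm = _loco_grm(cfg, g_all)
    chrom_, _, _ = cfg.parse_window()
    g = g_all.subset_variants(
        np.array([v.chrom == chrom_ for v in g_all.variants]))
    truth = json.loads((d / "truth.json").read_text())

    layers: dict[str, pd.Series] = {}
    logpeak = pd.read_csv(w / "pheno" / "log_peak.tsv", sep="\t")
    layers["protein_logpeak"] = pd.Series(logpeak["value"].to_numpy(),
                                          index=logpeak["animal_id"])
    expr = pd.read_csv(w / "chrompheno" / "expression_phenotype.tsv", sep="\t")
    layers["expression"] = pd.Series(expr["value"].to_numpy(),
                                     index=expr["animal_id"])
    cp = pd.read_csv(w / "chrompheno" / "chromatin_phenotypes.tsv", sep="\t",
                     index_col=0)
    excluded = set((w / "chrompheno" / "excluded_samples.txt").read_text().split())
    for peak in truth.get("target_peaks", []):
        if peak in cp.index:
            s = cp.loc[peak]
            layers[f"chromatin_{peak}"] = s[~s.index.isin(excluded)]

    outputs = []
    for name, series in layers.items():
        ids = [s for s in g.samples if s in set(series.index)]
        sub_g = g.subset_samples(ids)
        sub_grm = grm_subset(grm, ids)
        res = assoc.MixedAssociationScan(series.loc[ids].to_numpy(), sub_g,
                                         sub_grm, phenotype_name=name,
                                         grm_mode="loco").fit()
        path = out / f"qtl_{name}.tsv"
        cio.write_qtl_summary(res.summary_table, path)
        outputs.append(path)
    return outputs


def grm_subset(grm: assoc.Grm, sample_ids: list[str]) -> assoc.Grm:
    idx = [grm.sample_ids.index(s) for s in sample_ids]
    return assoc.Grm(list(sample_ids), grm.matrix[np.ix_(idx, idx)],
                     grm.n_variants_used, grm.excluded_region,
                     grm.n_monomorphic_skipped)


def _stage_coreg(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    w = Path(cfg.workdir)
    inputs = sorted((w / "assoc").glob("qtl_*.tsv")) if (w / "assoc").exists() else []
    if dry:
        return inputs
    out = w / "coreg"
    out.mkdir(parents=True, exist_ok=True)
    summaries = [cio.read_qtl_summary(p, name=p.stem.replace("qtl_", ""))
                 for p in inputs]
    results = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            results.append(coreg.qtl_correlation(summaries[i], summaries[j]))
    if len(summaries) >= 3:
        for extra in summaries[2:]:
            results.append(coreg.pseudo_r2([summaries[0], summaries[1], extra]))
    coreg.coreg_table(results).to_csv(out / "correlations.tsv", sep="\t",
                                      index=False)
    core = coreg.core_haplotype(summaries, q=cfg.q_core)
    core.membership.rename_axis("id").reset_index().to_csv(
        out / "core_haplotype.tsv", sep="\t", index=False)
    (out / "core_haplotype_ids.txt").write_text("\n".join(core.variant_ids) + "\n")
    return sorted(out.iterdir())


def _stage_tfbs(cfg: PipelineConfig, dry: bool = False) -> list[Path]:
    d = _data_dir(cfg)
    inputs = [d / "peak_sequence.fasta", d / "motif.pfm", d / "truth.json"]
    if dry:
        return inputs
    out = Path(cfg.workdir) / "tfbs"
    out.mkdir(parents=True, exist_ok=True)
    seqs = cio.read_fasta(d / "peak_sequence.fasta")
    pfms = cio.read_jaspar_pfm(d / "motif.pfm")
    pwms = [tfbs.pfm_to_pwm(m) for m in pfms]
    truth = json.loads((d / "truth.json").read_text())
    mv = truth["motif_variant"]
    var = VariantRecord(mv["id"], "seq", mv["pos"], mv["ref"], mv["alt"])
    name, seq = next(iter(seqs.items()))
    hits = []
    for pwm in pwms:
        hits.extend(tfbs.scan_sequence(pwm, seq, cfg.rel_score, name))
    tfbs.hits_to_frame(hits).to_csv(out / "hits.tsv", sep="\t", index=False)
    table = tfbs.allele_aware_sites(pwms, seq, var, mv["pos"] - 1,
                                    cfg.rel_score, cfg.tfm_p, name)
    table.to_csv(out / "allele_aware.tsv", sep="\t", index=False)
    return sorted(out.iterdir())


def run_all(cfg: PipelineConfig, force: bool = False) -> None:
    for stage in ("simulate", "pheno", "chrompheno", "assoc", "coreg", "tfbs"):
        run_stage(stage, cfg, force=force)


# ---------------------------------------------------------------------------
# In-memory demo
# ---------------------------------------------------------------------------

@dataclass
class DemoReport:
    """Everything the one-command demonstration computes."""

    seed: int
    threshold: float
    scans: dict
    variance_components: object
    correlations: pd.DataFrame
    core_haplotype: coreg.CoreHaplotype
    core_recall: float
    core_precision: float
    causal_in_core: bool
    causal_minus_log10p: dict
    conditional_max_core_logp: float
    conditional_table: pd.DataFrame
    ld_top_pair: float
    tfbs_table: pd.DataFrame
    truth: sim.SimTruth

    def to_markdown(self) -> str:
        lines = [
            "# Synthetic co-regulation demonstration",
            "",
            f"Seed {self.seed}; Bonferroni threshold {self.threshold:.3g}.",
            "",
            "## Per-layer scans",
            "",
            "| layer | top variant | beta | p | causal -log10(p) |",
            "|---|---|---|---|---|",
        ]
        for name, res in self.scans.items():
            top = res.summary_table.top_variant()
            lines.append(
                f"| {name} | {top['id']} | {top['beta']:.3f} | {top['p']:.3g} "
                f"| {self.causal_minus_log10p[name]:.1f} |")
        lines += [
            "",
            "## Repeated-measures protein model",
            "",
            "```",
            self.variance_components.summary(),
            "```",
            "",
            "## Co-regulation",
            "",
            self.correlations.to_markdown(index=False),
            "",
            f"Core haplotype: {len(self.core_haplotype)} variants "
            f"(recall {self.core_recall:.2f}, precision {self.core_precision:.2f} "
            f"vs the planted haplotype); causal variant "
            f"{'IS' if self.causal_in_core else 'is NOT'} a member.",
            f"LD R2 between top protein and top expression variants: "
            f"{self.ld_top_pair:.3f}.",
            f"Max core-variant -log10(p) after conditioning on the causal "
            f"variant: {self.conditional_max_core_logp:.2f}.",
            "",
            "## Predicted binding-site disruption",
            "",
            self.tfbs_table.to_markdown(index=False) if len(self.tfbs_table)
            else "(no sites)",
            "",
        ]
        return "\n".join(lines)


def demo(seed: int = 0, cfg: sim.SimConfig | None = None,
         q_core: float = 0.05, alpha: float = 0.05,
         outdir=None) -> DemoReport:
    """Simulate, analyse every layer, and report recovery of the planted truth."""
    cfg = cfg or sim.SimConfig(seed=seed)
    g, truth = sim.simulate_genotypes(cfg)
    cascade = sim.simulate_molecular_cascade(g, truth, cfg)
    causal = truth.causal_variant_ids[0]
    causal_pos = next(v.pos for v in g.variants if v.id == causal)

    # --- phenotypes ----------------------------------------------------------
    full_grm = assoc.compute_grm(g)
    A = pd.DataFrame(full_grm.matrix, index=full_grm.sample_ids,
                     columns=full_grm.sample_ids)
    rm = prot.RepeatedMeasuresModel(cascade.protein, A).fit()
    logs = prot.prepare_log_phenotypes(cascade.protein, ["peak"])
    layers: dict[str, pd.Series] = {"protein_logpeak": logs["peak"]}
    norm, _ = chrom.expression_normalize(cascade.expression.to_numpy())
    layers["expression"] = pd.Series(norm[0], index=cascade.expression.columns)
    pheno = chrom.chromatin_phenotypes(cascade.chip, cascade.chip_input)
    for peak in cascade.target_peaks:
        layers[f"chromatin_{peak}"] = pd.Series(pheno.phenotype(peak),
                                                index=pheno.sample_ids)

    # --- association: LOCO GRM, fine-mapping scan over the region ----------
    grm = assoc.compute_grm(g, exclude=sim.REGION_CHROM)
    g_region = g.subset_variants(
        np.array([v.chrom == sim.REGION_CHROM for v in g.variants]))
    threshold = assoc.bonferroni_threshold(alpha, g_region.n_variants)
    scans: dict[str, assoc.MlmaResult] = {}
    causal_logp: dict[str, float] = {}
    for name, series in layers.items():
        ids = [s for s in g.samples if s in set(series.index)]
        res = assoc.MixedAssociationScan(
            series.loc[ids].to_numpy(), g_region.subset_samples(ids),
            grm_subset(grm, ids), phenotype_name=name, grm_mode="loco",
        ).fit(threshold)
        scans[name] = res
        row = res.table[res.table["id"] == causal].iloc[0]
        causal_logp[name] = float(-np.log10(row["p"]))

    # --- co-regulation -------------------------------------------------------
    summaries = [r.summary_table for r in scans.values()]
    pairs = []
    for i in range(len(summaries)):
        for j in range(i + 1, len(summaries)):
            pairs.append(coreg.qtl_correlation(summaries[i], summaries[j]))
    for extra in summaries[2:]:
        pairs.append(coreg.pseudo_r2([summaries[0], summaries[1], extra]))
    corr_table = coreg.coreg_table(pairs)
    core = coreg.core_haplotype(summaries, q=q_core)
    truth_set = set(truth.core_haplotype_ids)
    found = set(core.variant_ids)
    recall = len(found & truth_set) / len(truth_set)
    precision = len(found & truth_set) / len(found) if found else float("nan")

    # --- conditional scan on the causal variant ------------------------------
    prot_series = layers["protein_logpeak"]
    ids = [s for s in g.samples if s in set(prot_series.index)]
    cond = assoc.conditional_scan(prot_series.loc[ids].to_numpy(),
                                  g_region.subset_samples(ids),
                                  grm_subset(grm, ids), condition_on=causal,
                                  phenotype_name="protein_logpeak|causal")
    core_rows = cond.table[cond.table["id"].isin(truth_set - {causal})]
    core_p = core_rows["p"].to_numpy()
    max_core_logp = (float(np.nanmax(-np.log10(core_p)))
                     if np.isfinite(core_p).any() else 0.0)

    ld_pair = coreg.ld_r2(g, scans["protein_logpeak"].summary_table.top_variant()["id"],
                          scans["expression"].summary_table.top_variant()["id"])

    # --- binding-site disruption fixture -------------------------------------
    pwm = tfbs.pfm_to_pwm(sim.SYNTHETIC_STAT_PFM)
    pwm.tf_id, pwm.tf_name = "SYN0001", "SYNSTAT"
    seq, var = sim.plant_motif(400, pwm, offset=180, variant_offset=4,
                               seed=cfg.seed + 17)
    tf_table = tfbs.allele_aware_sites([pwm], seq, var, var.pos - 1,
                                       rel_threshold=0.9, p_threshold=1e-4)

    report = DemoReport(
        seed=cfg.seed, threshold=threshold, scans=scans,
        variance_components=rm, correlations=corr_table,
        core_haplotype=core, core_recall=recall, core_precision=precision,
        causal_in_core=causal in found, causal_minus_log10p=causal_logp,
        conditional_max_core_logp=max_core_logp, conditional_table=cond.table,
        ld_top_pair=ld_pair, tfbs_table=tf_table, truth=truth)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.md").write_text(report.to_markdown())
        corr_table.to_csv(out / "correlations.tsv", sep="\t", index=False)
        for name, res in scans.items():
            cio.write_qtl_summary(res.summary_table, out / f"qtl_{name}.tsv")
        (out / "core_haplotype.txt").write_text("\n".join(core.variant_ids) + "\n")
    return report
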