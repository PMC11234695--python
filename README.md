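# coregqtl

Multi-layer molecular QTL co-regulation analysis: linking chromatin
accessibility, histone modification, gene expression and protein
concentration QTL at a shared locus.

## The problem

Milk protein concentrations (the motivating case is lactoferrin, an
antimicrobial whey protein whose concentration varies by orders of magnitude
between cows) are partly under genetic control. When a protein QTL (pQTL), a
*cis* expression QTL (eQTL) for the encoding gene, and chromatin QTL
(histone-modification hQTL from ChIP-seq, accessibility caQTL from ATAC-seq)
all map to the same window, the question becomes: are they the *same*
signal — a regulatory chain from open chromatin through transcription to
protein — and which variants carry it? `coregqtl` is for quantitative
geneticists who want that whole chain as one tested pipeline:

1. **Phenotype construction** — a repeated-measures mixed model
   `y = Xb + Za + Zp + e` (animal effect `a ~ (0, A σ²_a)`, permanent
   environment `p`, residual `e`) aggregating repeated protein records into
   one value per animal (the additive BLUP plus mean residual); sample
   skewness `b₁ = Σ(xᵢ−x̄)³/(n·s³)` and natural-log transforms; chromatin
   phenotypes from read counts via depth normalisation
   (`tᵢ = Σⱼ Cᵢⱼ`, `fᵢ = tᵢ/mean(t)`, `Cᴺ = C/f`), peak quality filters,
   and per-peak residuals of `log(Cᴺ+1)` on the matched input
   `log(Iᴺ+1)`; a size-factor + log surrogate of the variance-stabilising
   transformation for expression counts.
2. **Association** — a VanRaden-1 genomic relationship matrix, REML
   heritability (`y ~ N(Xb, σ²_g G + σ²_e I)` via eigendecomposition of G),
   and mixed-linear-model association (MLMA) with leave-one-chromosome-out /
   leave-one-segment-out GRMs, covariates, and conditional single-variant
   scans.
3. **Co-regulation** — Pearson/Spearman correlations of allele effects (β)
   and −log₁₀(p) between QTL layers, the PCA pseudo-R² (`λ₁/Σλ` of a
   triplet's correlation matrix), the core haplotype (variants in the top
   5% by |β| of *every* layer), LD R², variant–peak overlap and
   variant-density percentiles.
4. **TFBS scanning** — JASPAR PFMs to log₂-odds PWMs, both-strand scanning
   with `relScore = (s−min)/(max−min) ≥ 0.9`, exact score-distribution
   (TFM) p-values by dynamic programming, and allele-aware disruption
   scores at candidate variants.

Because the motivating study's animal data are not downloadable at desk
scale, the package ships a first-class synthetic-data generator
(`coregqtl.simulate`) that emulates the causal cascade — an F2 population
with LD-blocked genotypes, a common (MAF ≈ 0.45) core haplotype of tightly
linked variants, negative-binomial ChIP/ATAC counts with paired inputs, and
repeated protein measures with a 0.56 natural-log per-allele effect and
heritability 0.4 — so every stage is testable against planted truth.

## Worked example

Simulate a population, build the log-peak protein phenotype, and scan the
fine-mapping region with a LOCO mixed model:

```python
import numpy as np
from coregqtl import SimConfig, simulate_genotypes, simulate_molecular_cascade
from coregqtl.association import compute_grm, mlma, bonferroni_threshold
from coregqtl.pipeline import grm_subset
from coregqtl.protein import prepare_log_phenotypes, effect_to_fold

cfg = SimConfig(seed=7, n_animals=400, n_variants=800, n_background_variants=600)
g, truth = simulate_genotypes(cfg)
cascade = simulate_molecular_cascade(g, truth, cfg)

logpeak = prepare_log_phenotypes(cascade.protein, ["peak"])["peak"]
ids = [s for s in g.samples if s in set(logpeak.index)]
grm = compute_grm(g, exclude="22")            # leave-one-chromosome-out
region = g.subset_variants(np.array([v.chrom == "22" for v in g.variants]))
res = mlma(logpeak.loc[ids].to_numpy(), region.subset_samples(ids),
           grm_subset(grm, ids), phenotype_name="log_peak", grm_mode="loco",
           threshold=bonferroni_threshold(0.05, region.n_variants))
print(res.summary())
top = res.summary_table.top_variant()
print("fold change per allele:", effect_to_fold(float(top["beta"]), 1))
```

prints

```
MLMA scan: phenotype='log_peak' grm_mode=loco covariates=[]
  variants tested  : 800 of 800
  null h2          : 0.2944
  top variant      : rs1000390 at 22:52941987  beta=0.5509 (SE 0.0668)  p=1.69e-16
  threshold        : 6.25e-05  (20 significant)
fold change per allele: 1.73
```

The top variant's β of 0.55 natural-log units recovers the planted 0.56
per-allele effect (a 1.73× higher concentration per allele), at p far below
the Bonferroni threshold; the 20 significant variants are the planted core
haplotype. `rs1000390` is indeed a member of `truth.core_haplotype_ids`.

The whole chain — all four QTL layers, correlations, pseudo-R², core
haplotype recovery, a conditional scan on the causal variant, and the
binding-site disruption table — runs as one command:

```sh
coregqtl demo --seed 0 --outdir demo_out    # writes demo_out/report.md
```

Staged runs with provenance sidecars (`simulate`, `pheno`, `chrompheno`,
`assoc`, `coreg`, `tfbs`, `run-all`) operate on files in a working
directory; see `coregqtl --help`.

## Layout

- `src/coregqtl/datatypes.py` — containers (GenotypeMatrix, PeakSet,
  CountMatrix, QtlSummary) and the 1-based inclusive coordinate convention
- `src/coregqtl/io.py` — VCF, BED/narrowPeak/broadPeak, count TSVs, JASPAR
  PFM, FASTA, QTL summary TSVs
- `src/coregqtl/protein.py`, `chromatin.py` — phenotype construction
- `src/coregqtl/association.py` — GRM, REML, MLMA, conditional scans
- `src/coregqtl/coreg.py` — correlations, pseudo-R², core haplotype, LD,
  overlap, density percentiles
- `src/coregqtl/tfbs.py` — PWM scanning and exact p-values
- `src/coregqtl/simulate.py` — the synthetic cascade generator
- `src/coregqtl/pipeline.py`, `cli.py` — staged orchestration and the CLI
- `docs/methods.md` — models, assumptions, parameter choices, limitations
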