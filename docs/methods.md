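# Methods

`coregqtl` implements a multi-layer molecular QTL co-regulation analysis: it
asks whether the same genetic signal drives a protein concentration QTL
(pQTL), a *cis* expression QTL (eQTL), and histone-modification / chromatin
accessibility QTL (hQTL / caQTL) at a shared locus, and then narrows the
signal to a core haplotype and candidate regulatory variants inside open
chromatin. This note describes the models, the choices made where the design
was genuinely open, and what the synthetic data generator does and does not
emulate.

## Phenotype construction

### Protein (repeated measures)

Milk protein concentration is measured up to three times per lactation
(periods *peak*, *mid*, *late*; mg/L). Sample skewness is assessed with the
third-moment estimator `sum((x - mean)^3) / (n s^3)`, where `s` uses the
n−1 denominator (the standard sample definition; the source of the data does
not pin the denominator down further). Because raw concentrations are
strongly right-skewed, per-period phenotypes are natural-log transformed.

The aggregate phenotype comes from the repeated-measures mixed model

    y = X b + Z a + Z p + e,
    a ~ N(0, A σ²_a),  p ~ N(0, I σ²_pe),  e ~ N(0, I σ²_e)

with fixed effects for the collection period plus any user-supplied
covariate columns (covariates are deliberately generic: the synthetic
population has no breed structure, so nothing breed-specific is hard-coded),
a relationship-structured additive animal effect `a` (pedigree A or a GRM),
and an i.i.d. permanent-environment effect `p`. The per-animal aggregate is
the additive BLUP plus the mean of that animal's residuals; whether the PE
BLUP is included is a flag (default excluded — the aggregate is meant to
carry the additive signal plus un-modelled individual deviation, and the PE
term is a nuisance shared across records). The aggregate is centred near
zero and is never log-transformed (it contains negative values by
construction; the API refuses).

REML here maximises the restricted likelihood directly, by Nelder–Mead on
the log-variances, using the q-dimensional Woodbury form of `V^{-1}` and the
matrix determinant lemma so each evaluation costs one q×q factorisation
(q = number of animals). We chose direct maximisation over
average-information updates because at q ≤ ~700 each likelihood evaluation
is milliseconds, AI buys no asymptotic advantage, and a derivative-free
search is more robust near the σ² = 0 boundary; the best-so-far likelihood
trace is recorded and is non-decreasing by construction. Convergence follows
Nelder–Mead's simplex tolerances (1e-9 on parameters, 1e-10 on the
objective, 400 iterations). With identity A and one record per
animal×period, σ²_a and σ²_pe are not separately identifiable; the model
accepts `include_pe=False` for that case.

The heritability SE uses the delta method on the numeric Hessian of the
restricted likelihood in log-variance coordinates. The LRT against
σ²_a = 0 is referred to the 50:50 mixture of a point mass at zero and χ²₁
(variance component on the boundary), reported as `0.5 · P(χ²₁ > LRT)`.

Log effects are converted to fold changes as `exp(β·n_alleles)` to three
significant figures: a 0.56 natural-log per-allele effect is a 1.75× fold
change per allele.

### Chromatin (ChIP-seq / ATAC-seq)

Counts over consensus peaks (peaks × samples) for both the pulldown and a
matched input are depth-normalised: per-sample totals `t_j`, relative
factors `f_j = t_j / mean(t)`, adjusted counts `C^N = C / f` columnwise. The
reference `mean(t)` is an arbitrary scale constant and can be pinned
(`reference_depth`), which makes the normalisation exactly invariant to
rescaling any single sample's raw counts — the property the normalisation
exists to provide.

Peak quality filters, applied simultaneously to the unfiltered set: a peak
is removed when its length-adjusted count (total reads / peak length in
bases) falls strictly below the 1st percentile of all peaks (percentile by
linear interpolation between order statistics), or when its length-adjusted
*input* count exceeds 5× the mean across peaks (reference-assembly artefact
pile-ups). The 5× rule is one reading of an ambiguous description ("5× the
average"); we interpret the average as the mean length-adjusted input count
across peaks.

The hQTL/caQTL phenotype is the residual of the per-peak OLS regression
`log(C^N + 1) = a + b·log(I^N + 1) + e` (natural logs) across samples. A
peak whose input covariate is constant falls back to an intercept-only model
(residuals = centred log counts) and is flagged; this is also the path used
for assays with only a consensus (pooled) input, which is represented as a
single input column broadcast to all samples.

Outlier samples are excluded by PCA on centred, unscaled data (features
share units): any sample farther than 4 SD from the mean on any of the first
7 components (6 for expression) is dropped in a single pass.

### Expression

Expression counts are normalised by median-of-ratios size factors followed
by `log2(count/sf + 1)`; TPM is available given gene lengths. This is a
deliberate, documented surrogate for the exact DESeq2 variance-stabilising
transformation, isolated behind one function so an alternative backend can
be swapped in; its purpose here (removing depth and compressing the
right tail so skew does not inflate false positives) is what the tests
verify.

## Association

The GRM is VanRaden method 1 (GCTA's default): per-variant standardised
dosages `z = (x − 2p)/sqrt(2p(1−p))`, `G = ZZ'/m`, with monomorphic variants
skipped and missing dosages mean-imputed at the point of use only. LOCO /
LOSO designs exclude the scan chromosome or segment from the GRM so the
tested signal is not absorbed by the polygenic term.

REML for `y ~ N(Xb, σ²_g G + σ²_e I)` uses the one-time eigendecomposition
of G: after rotation the covariance is diagonal in `h² d_i + (1 − h²)`, the
total variance is profiled out, and the restricted likelihood is maximised
over h² by a coarse grid plus bounded refinement (the profile can be
multi-modal). The h² SE is the inverse curvature of the profile likelihood
at the optimum; the boundary LRT uses the same mixture reference as above.

MLMA estimates variance components once under the null (the behaviour of
genome-scan tools; it is what makes scans tractable), then tests each
variant by GLS under the fitted `V`: covariates and dosages are whitened and
projected, β is per alt-allele copy, and the Wald p-value uses the standard
normal (samples number in the hundreds; no small-sample correction).
Monomorphic variants are reported with a status flag rather than dropped,
as are variants numerically collinear with the covariates (relevant in
conditional scans, where perfect proxies of the conditioning variant carry
no testable residual variation). Conditional scans append the conditioning
variant's dosage to the covariates and flag its own row.

Significance uses the Bonferroni threshold `α/m` (0.05/631896 = 7.9×10⁻⁸ at
two significant figures for the genome-wide marker count this pipeline
emulates).

## Co-regulation

Two QTL summaries are compared after an inner join on variant id with
allele-orientation harmonisation (β sign flips when ref/alt are swapped):
Pearson and Spearman correlations of the β vectors and of the −log10 p
vectors within a window. For a triplet of summaries, the pseudo-R² is the
fraction of variance on the first principal component, `λ₁/Σλ`, of the 3×3
correlation matrix by default — β scales differ across molecular layers, so
standardisation is the sensible default; a covariance mode is provided
because either convention is defensible, and on our synthetic data the two
differ by ≲0.02. For a pair, the correlation-mode value degenerates to
`(1 + |r|)/2`.

The core haplotype intersects the per-QTL top `⌈q·N⌉` variants by |β|
(default q = 0.05) over a common variant universe, with deterministic tie
breaking (smaller p, then variant id — a quantile rule had to be fixed and
this one is reproducible). LD is the squared Pearson correlation of dosage
vectors over samples non-missing at both variants. Variant–peak overlap is
inclusive containment on 1-based coordinates. Variant-density percentiles
rank a focus window's density against genome-wide per-window counts by the
"fraction strictly lower × 100" rule, so a window equal to every other
scores 0 and one denser than all scores 100; singleton variants should be
removed by the caller before counting.

Two windowing conventions (a fixed interval around the gene, or ±N kb of
the TSS) exist in the source material with inconsistent descriptions; both
are supported (`in_window` plus caller-specified intervals) and neither is
privileged.

## TFBS scanning

PFM → PWM conversion follows the JASPAR/TFBSTools convention:
`log2((count + 0.8·bg_b)/(total + 0.8)/bg_b)` with a uniform background by
default. Scanning scores every offset on both strands (− strand via the
reverse-complement matrix, reported at the + strand start of the covered
window, BED-style); windows containing N are skipped; `relScore` rescales
the raw score to [0, 1] between the matrix minimum and maximum.

The TFM p-value is the exact tail probability `P(score ≥ s)` under the
i.i.d. background. For matrices whose state count permits it the dynamic
programme runs over exact floating-point partial sums (ties handled
identically to exhaustive enumeration); wider matrices fall back to a
fixed-step discretized convolution whose error is bounded by
width × granularity (default 1e-4) in score units. The lazy-refinement
machinery of the original exact-p-value algorithm is unnecessary at these
widths. P-values are always reported at full precision; no flooring
convention is applied.

Allele-aware scoring scans both the reference and the alternate sequence,
keeps hits covering the variant that pass `relScore ≥ 0.9` and
`TFM p ≤ 1e-5` under *either* allele, and reports per-allele raw scores and
`delta = alt − ref` (antisymmetric under allele swap).

## Synthetic data generator

The generator emulates the causal cascade the analysis assumes — regulatory
variants in open chromatin → gene expression → protein concentration — in an
F2-cross population:

- **Genotypes.** Two founder pools with blockwise-divergent allele
  frequencies; each animal draws two gametes whose pool membership is
  redrawn per LD block (free recombination between blocks); within a block,
  variants copy a latent block state with a flip probability growing with
  distance, so LD decays along the block. Defaults: 650 animals, 2000
  region variants in ~50-variant blocks across a ~2 Mb window, plus 1000
  unlinked background variants on a second chromosome. The background
  chromosome exists because the emulated design builds its GRM from
  genome-wide markers while fine-mapping a single window: without it a
  leave-one-chromosome-out GRM cannot be formed and the polygenic effect
  would recreate the focal signal through the relationship matrix.
- **Core haplotype.** 20 consecutive variants around a single causal variant
  at MAF ≈ 0.45, pairwise dosage R² ≥ 0.99 enforced by construction (each
  member differs from the causal gamete vector by at most two gamete flips,
  reverted if sampling noise breaches the floor). A small flank (2 variants
  per side, r² ≲ 0.25 with the causal variant) provides a realistic LD
  shoulder and a target for conditional-scan behaviour at moderate LD.
- **Counts.** ChIP/ATAC counts are negative binomial (dispersion 10) with a
  baseline, a peak-length term, a per-sample lognormal depth term
  (σ = 0.3 on the log scale), and `α_chromatin·dosage` (default 0.5) on the
  target peaks only; input counts share the structure but carry no genetic
  effect — the generator deliberately produces exactly the nuisance the
  depth normalisation and input regression exist to remove. Expression is
  analogous with `α_expression` (0.5) on the target gene among 200 genes.
- **Protein.** `value = exp(μ_t + α_protein·dosage + a + pe + e)` with
  α_protein = 0.56 (the per-allele natural-log effect the pipeline should
  recover), period means μ ordered peak < late < mid (ln 66, ln 181,
  ln 164 mg/L), a polygenic `a` drawn from the background-chromosome GRM
  scaled so the polygenic log-scale heritability is 0.4 given
  σ²_pe = 0.05 and σ²_e = 0.35, and ~10% of records missing at random
  (every animal keeps at least one).

What the generator does **not** emulate: realistic recombination maps or
pedigree loops, breed composition and heterosis covariates, shared
biological variation between ChIP marks beyond the planted effect,
sequence-level mutation processes, and the severe sample-size asymmetry of
real chromatin assays (it genotypes every layer on every animal). Passing
tests therefore demonstrate that the statistical machinery recovers a known
cascade under idealised nuisance structure — not that real ChIP-seq QC or
population structure is handled.

All randomness descends from one seed through spawned generator streams;
two runs with equal configs are bit-identical, and the fixture bundle's
manifest checksums are stable across runs.

## Problem sizes and numerical choices

Test and demonstration sizes are chosen to keep the full suite in a couple
of minutes on one core: the end-to-end demonstration and acceptance runs
use the default 650 animals × 2000 region variants; REML calibration uses
100 replicates at n = 600; planted-recovery properties use 12–20 seeds;
repeated-measures recovery uses 250 animals × 8 replicates. Degenerate
inputs are handled explicitly rather than numerically: constant phenotypes,
monomorphic variants, zero-total samples, constant regression covariates,
all-zero genes and empty peak sets raise or flag as documented above.

## Known limitations

- The two-variance-component REML profiles over a single ratio; models with
  several genomic components are out of scope.
- MLMA's null-model variance components are not re-estimated per variant;
  for very large single-variant effects this slightly deflates
  significance (the standard trade-off of the approach).
- The expression normalisation is a surrogate, not the exact DESeq2 VST.
- The TFM p-value assumes an i.i.d. (zero-order) background; dinucleotide
  backgrounds are not supported.
- Colocalization here is correlational (correlations, pseudo-R², set
  intersection); no posterior colocalization probabilities are computed.
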