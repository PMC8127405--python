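# Methods

This note documents the statistical procedures implemented in `gers`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Scoring model

### TWAS statistic

For a feature (one gene in one SNP-weight panel) with harmonized weight
vector *w* over its cis variants, GWAS Z-scores *z* and reference LD matrix
*V*, we compute the weighted-burden statistic
*Z*<sub>TWAS</sub> = *w*ᵀ*z* / √(*w*ᵀ*V w*), with a two-sided normal
P-value. Under the null (z drawn from MVN(0, V)) the statistic is standard
normal, which the test suite verifies by simulation (2000 features,
Kolmogorov–Smirnov at α = 0.01).

Numerical choices:

- **LD ridge.** 1×10⁻³ is added to the diagonal of every LD block before
  the quadratic form. Cis blocks estimated from a few hundred reference
  samples are frequently near-singular; the ridge bounds the denominator
  away from zero and changes the statistic by O(10⁻³) relative error,
  far below the reporting precision. Features whose quadratic form is
  ≤ 10⁻¹² even after the ridge are recorded as non-imputable and skipped.
- **Missing weight variants.** Variants present in a weight file but
  absent from the harmonized universe are dropped without refitting.
  A feature that loses more than 50% of its absolute weight mass during
  harmonization is treated as non-imputable rather than scored from a
  remnant of its predictor.
- **Zero-variance variants** in the reference are excluded from LD blocks
  with a warning; the caller's weight vector is subset accordingly.

### Expression imputation and reference standardization

Predicted expression is the linear predictor GeneExp<sub>ig</sub> =
Σ<sub>j</sub> X<sub>ij</sub>β<sub>gj</sub>. Missing genotypes are
mean-imputed as twice the *reference* allele frequency, never the target
frequency, so that target-sample composition cannot leak into scores. Each
feature is centred and scaled by its mean and SD (denominator n−1; the
choice is immaterial as long as it is consistent) in the reference panel;
features with reference SD ≤ 10⁻⁸ are dropped everywhere. Standardization
is per panel, matching the per-panel score construction.

### GeRS construction

Within each panel, features are processed in three steps:

1. **MHC reduction.** Among features whose gene boundaries overlap
   chr6:28–34 Mb, only the smallest-P feature is kept (ties: larger |Z|,
   then lexicographic feature id). This runs *before* generic clumping
   because the long-range LD of the region defeats the pairwise R²/window
   logic.
2. **Expression clumping.** Greedy by ascending TWAS P: a candidate is
   removed when its reference predicted expression has squared correlation
   > 0.9 with an already-retained feature whose gene boundaries lie within
   500 kb. The window is measured between boundary *intervals*
   (closest-edge distance), whereas variant clumping below uses
   point-to-point distance — genes have extent, variants do not.
3. **Thresholding and aggregation.** For each threshold in
   {1, 0.5, 0.1, 0.05, 0.01, 10⁻³, 10⁻⁴, 10⁻⁵, 10⁻⁶}, the score is the
   TWAS-Z-weighted sum of standardized expression over surviving features
   with p ≤ t. Feature sets are nested by construction. Each final column
   is again centred/scaled by its reference-sample mean/SD; thresholds with
   no features are omitted.

Because every step is linear, each GeRS column is equivalent to a
per-variant score with collapsed weights
w<sub>j</sub> = Σ<sub>g</sub> Z<sub>g</sub> β<sub>gj</sub>/sd<sub>g</sub>
up to an additive constant; the suite asserts this duality to 10⁻⁸, which
guards the whole chain (imputation, standardization, aggregation) at once.

Stratified variants: *coloc* keeps features with colocalization posterior
PP4 strictly above 0.8 (PP4 is consumed as input, never computed here;
features lacking PP4 are excluded, and a missing PP4 on a feature with
TWAS P < 0.05 is an input error since colocalization is expected to have
been run for those). *Tissue-specific* keeps features whose gene either has
no significantly cis-heritable feature in the opposite tissue class
(blood vs non-blood) or whose reference predicted expression has R² < 0.01
with every same-gene feature there. The heritability-significance cutoff
for "significantly heritable" is hsq_p < 0.01 — the weight-set indexes
carry a cis-h² P-value but no canonical threshold, so this is a documented
package choice. Scores are standardized before entering any multi-score
model.

### PRS baselines

pT+clump: greedy LD clumping at R² > 0.1 within 250 kb (point distance),
single most significant variant retained in chr6:28–34 Mb, thresholds
{10⁻⁸, 10⁻⁶, 10⁻⁴, 10⁻², 0.1, 0.2, 0.3, 0.4, 0.5, 1}. A sensitivity mode
disables the MHC rule; its effect is confined to MHC-derived variants by
construction and by test. Scores are computed on the Z scale (β := Z):
the evaluation metric is a correlation and therefore invariant to any
deterministic per-variant rescaling convention, and this avoids carrying
per-variant sample sizes. Gene-region-restricted PRS keep variants within
a configurable flank (default 500 kb) of supplied gene intervals.
Externally computed scores (e.g. continuous-shrinkage PRS) are ingested
from FID/IID-keyed tables and re-standardized against reference rows when
present.

### Harmonization

The variant universe is the intersection of reference panel, target panel
and sumstats ids, optionally restricted to a HapMap3-style id list.
Orientation is the reference panel's A1: swapped-allele records have Z or β
negated (and genotype counts recoded 2−x); irreconcilable allele pairs are
dropped. Strand-ambiguous (A/T, C/G) variants are removed at sumstats read
time, as munging pipelines do. Variant matching is by id (rsID or
positional); a pairwise overlap below 1% raises a mismatch error rather
than silently scoring a near-empty universe. The invariant that flips
anywhere leave all downstream scores unchanged is asserted to 10⁻¹⁰.

Genotype QC follows standard hard-call practice: calls require a genotype
probability strictly above 0.9 (else missing); variants fail on MAF
< 0.001, missingness > 0.05, or Hardy–Weinberg χ² P < 10⁻⁶. The χ²
approximation is used rather than the exact test; at this threshold and
n ≥ 500 the two disagree only in regimes where both reject.

## Evaluation

Prediction accuracy is Pearson's r between observed phenotype and
out-of-sample prediction, SE = √((1−r²)/(n−2)). Single-score models use a
GLM (linear or logistic); multi-score models use an elastic net under
nested CV: outer 5-fold (stratified for binary traits) yields one
prediction per individual; for each outer fold an inner 10-fold CV on the
training portion selects the mixing parameter from {0.1, 0.55, 1.0} and
the penalty from a 25-point log-spaced path anchored at the data-derived
maximum. The selected model is refit on the full outer-training portion.
Fold assignment is seeded and recorded. If the selected model is empty,
the fold falls back to an intercept-only prediction with a warning.

Binary traits: single-score models use logistic regression and are
evaluated on the linear predictor. Multi-score elastic nets are fit on the
0/1 indicator with the linear (squared-error) objective — a
linear-probability working model — and likewise compared on the linear
predictor. This keeps inner-CV selection aligned with the correlation
metric used throughout; for score combination the ranking it induces is
essentially identical to deviance-based selection. No covariates enter any
prediction model; with ancestry-unstructured synthetic data there is
nothing to adjust for, and on real data users should residualize upstream.

Two models predicting the same phenotype are compared with the
Hotelling–Williams t (df = n−3), with the correlation between the two
models' prediction vectors supplied to account for their dependence;
two-sided P. The n is the full concatenated-prediction sample size. The
implementation is validated against an independently written second
implementation, a permutation oracle (random per-sample swapping of the
two predictors), and a null calibration study (two equally informative
scores, n = 500, 1000 replicates: rejection rate at α = 0.05 must fall in
the exact binomial 99% interval). For a GeRS-vs-PRS comparison the ratio
r_GeRS/r_PRS is also reported; it may legitimately exceed 1.

## Synthetic data

The generator emulates the statistical structure the method assumes, at
desk scale:

- **Genotypes.** Haplotypes threshold a latent Gaussian AR(1) process with
  correlation exp(−λ·gap) between neighbours (λ = 10⁻⁵/bp by default);
  MAF ~ Uniform(0.05, 0.5); diploids pair consecutive haplotypes. The
  *allelic* correlation implied by dichotomization is the tetrachoric-
  attenuated value, which the tests compute in closed form from the
  bivariate normal CDF rather than pretending the latent coefficient
  carries over. Gene windows (100 kb, 6 variants) are spaced 1.2 Mb apart
  so cis blocks are effectively LD-independent, except for a pseudo-MHC
  block on chromosome "6": ten overlapping gene intervals over one dense
  40-variant, high-LD run inside 28–34 Mb, present to exercise the MHC
  rules.
- **Weight sets.** 1–5 causal cis variants per gene; per-panel effect
  vectors share a common component giving cross-panel correlation
  `cross_tissue_r` (default 0.6, "moderately correlated" tissues); cis-h²
  ~ Uniform(0.05, 0.4); weight files carry training noise with SD
  √((1−h²)/n_train) on the standardized-genotype scale (n_train = 300 by
  default, typical of expression panels). The emitted hsq_p is a
  plumbing-grade χ² approximation — adequate for exercising
  heritability-significance filters, not an estimator to be interpreted.
- **Phenotype and GWAS.** The phenotype is the sum of a mediated component
  (gene effects × cis-genetic expression in the causal tissue, variance
  h²·mediated_frac), direct variant effects (variance h²·(1−mediated_frac))
  and Gaussian noise. Defaults h² = 0.5, mediated_frac = 0.4, half of the
  genes null. GWAS Z-scores come from per-variant regression in an
  independently simulated cohort (n = 20 000), so sumstats–target
  independence holds by construction. Cohort sizes default to 500
  (reference, 1KG-EUR-sized), 5000 (target) and 20 000 (GWAS).

What the simulator does **not** model: ancestry structure, recombination
maps or realistic LD beyond AR(1), imputation uncertainty, binary-trait
ascertainment, trans-eQTLs, and horizontal pleiotropy beyond the
direct-effect component. Passing tests therefore demonstrate the
*machinery* — harmonization, scoring algebra, CV hygiene, statistical
calibration, and qualitative mediation recovery — not performance on real
cohort data.

The mediation-recovery analysis holds one seed fixed across
mediated-fraction settings {0.2, 0.5, 0.8}, so genotypes and effect
architectures are identical and only the variance split changes; the
squared ratio (r_GeRS/r_PRS)² is then required to increase strictly, and
restricting GeRS to truly mediating genes must beat restricting to null
genes — the synthetic twin of a colocalization-restricted heritability
analysis.

## Problem sizes and determinism

Default experiment sizes (2 panels, 40 genes + 10 MHC genes, ~280
variants, target 5000, GWAS 20 000) were chosen so that a full sweep plus
calibration studies completes in minutes on one CPU while keeping GWAS
power high enough that clumping, thresholding and the elastic net all
operate in their intended regimes. All randomness flows from explicit
integer seeds through per-stage `numpy` generators; fixtures are
bit-reproducible, which the suite checks at the `.bed`-byte level.

## Known limitations

- PP4 and continuous-shrinkage PRS are consumed, never computed.
- No summary-statistic imputation, conditional/joint TWAS, omnibus
  multi-tissue test, or liability-scale conversions.
- The PLINK-1 reader handles the variant-major layout only (universal
  since PLINK 1.07) and loads genotypes densely; it is meant for
  desk-scale panels, not biobank files.
- Cross-panel feature clumping is deliberately absent: clumping operates
  within a SNP-weight set, so splicing-style panels with several features
  per gene retain their redundancy (and the evaluation layer's elastic net
  is what absorbs it).
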