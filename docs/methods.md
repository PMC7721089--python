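# Methods

This note documents the statistical procedures implemented in
`m6ametab`, the defaults they use, what the synthetic-cohort generator
does and does not emulate, and the design decisions taken where the
published conventions leave room.

## Modification-pattern clustering

Tumors are clustered on the 20-gene regulator panel (the curated
23-gene panel minus the IGF2BP readers, which are unreliably
quantified across platforms). Each gene is standardized to mean 0 /
SD 1 before clustering — k-means on raw log2 values would be dominated
by highly expressed regulators — and zero-variance genes are dropped
with a warning.

The cluster count is selected by a majority vote of four internal
validity indices evaluated for every k in 2..15: silhouette width
(max), Calinski–Harabasz (max), Davies–Bouldin (min) and the gap
statistic (max; Tibshirani's uniform-box reference, B = 10 draws).
The original consensus approach polls ~30 indices; four
well-conditioned indices with a configurable index set preserve the
consensus design at tractable cost. Ties vote for the smaller k.
K-means itself is Lloyd's algorithm, best of `nstart = 25` random
initializations, tolerance 1e-6, at most 300 iterations. Labels are
renumbered so that cluster 1 has the lowest and cluster k the highest
mean feature value, giving stable C1 = low-regulator / C3 =
high-regulator semantics across runs and cohorts.

On correlated matrices such as enrichment-score panels the gap
statistic's uniform-box reference is known to over-estimate k; it then
simply loses the vote to the other three indices.

## Single-sample enrichment

The enrichment statistic follows the GSVA recipe. Per gene, each
sample's value is replaced by an estimate of its cumulative density
across samples: a Gaussian-kernel CDF with bandwidth sd/4 (floored at
machine epsilon, so constant genes map to 0.5), or the empirical CDF.
Genes are then ranked within each sample (ties broken by gene-symbol
lexicographic order for bit-reproducibility) and assigned the
symmetric rank statistic r = |G|/2 − rank + ½. For each gene set a
walk over the ranked list adds |r|^tau (normalized by the in-set
total) at in-set genes and subtracts 1/(|G| − |set|) elsewhere. The
default score is the signed sum of the maximum positive and minimum
negative deviation, bounded in [−1, 1]; `max_deviation` mode returns
the single largest-magnitude deviation (magnitude ties resolve to the
positive side). Defaults: Gaussian kernel, tau = 1, set-size bounds
[5, 500]. A degenerate set containing only zero-weight (exact
mid-rank) genes walks with uniform in-set weights.

The implementation is validated against an independent step-by-step
walk oracle on all instances with ≤ 8 genes and ≤ 3-member sets
(exact to 1e-12), and ecdf-kernel scores are checked to be invariant
under strictly monotone per-gene transforms.

## Differential expression

Pattern contrasts use an empirical-Bayes moderated t-test on the
log2-scale matrix: per-gene pooled variances are shrunk toward a
prior whose scale and degrees of freedom are estimated from the
marginal distribution of log s² by digamma/trigamma moment matching;
the moderated t is referred to a t distribution with d0 + d_g degrees
of freedom. A cross-check test reproduces the Bioconductor limma
results on shared inputs (identical fold changes, t correlation
> 0.999). DEGs require BH-adjusted p < 0.05 and |log2FC| strictly
greater than 1. With three clusters the DEG set is the union of all
pairwise contrasts (each BH-adjusted separately); a one-vs-rest mode
is provided since either reading of "between patterns" is defensible.

## Signature and m6Ascore

Each DEG is screened with a univariate Cox proportional-hazards model
on overall survival (unscaled log2 expression as sole covariate,
Breslow tie handling via lifelines); genes with Wald p < 0.05 form the
signature, split at HR = 1 into risk and protective sides. "Scaled
between −1 and 1" is implemented as per-gene min–max scaling — the
only affine map achieving exactly that range — applied after the Cox
screen, matching the published order of operations. The scaling
bounds are frozen in the signature file so external cohorts can be
scored against the discovery cohort's reference frame (a per-cohort
rescaling option exists). The m6Ascore is the sum of scaled risk-gene
values minus the sum of scaled protective-gene values; cohorts are
split at the median score, with scores exactly at the median assigned
to the low group for determinism.

## Survival analytics

Kaplan–Meier estimation, the unweighted log-rank test and
multivariate Cox fits are delegated to lifelines; Greenwood variances
are attached to each curve. The nomogram converts a fitted
multivariate model (default factors: score group high vs low, TNM
stage as ordinal categorical with stage i reference, age continuous)
into points: per factor, 100 · β_f(x − x_ref) / max_f range(β_f x),
so the widest factor spans exactly 0–100; total points map to
predicted survival at each horizon through the model's baseline
survival. Horizons beyond observed follow-up are refused rather than
extrapolated. Time-dependent AUC is the IPCW cumulative-case /
dynamic-control estimator (scikit-survival), reported at 1/3/5 years.

## Synthetic cohort generator

The generator defines the study conditions for all tests. Expression
is drawn directly on the log2 scale (no count layer), gene baselines
uniform on [3, 9], i.i.d. Gaussian noise with SD 1.

* **Patterns.** A latent pattern index z ∈ {1, 2, 3} with equal
  proportions (n = 300 by default).
* **Regulators.** Role-specific per-pattern mean profiles in units of
  `regulator_shift` (default 1.5 log2 units): readers (0, 1, 0.35),
  writers (0, 0.1, 1), erasers (0, 0.5, 1). Patterns 1 vs 2 therefore
  differ mostly in readers and patterns 1/2 vs 3 mostly in writers,
  overall regulator expression rises from pattern 1 to 3, and the
  three pattern centroids are near-equidistant in regulator space.
  The equidistance is deliberate: the patterns are distinct cell
  states, not points on one gradient, and a single linear gradient
  would be read as two clusters by variance-ratio validity indices.
* **Prognostic genes.** 40 risk genes with mean shift · z and 40
  protective genes with shift · (2 − z), so risk genes rise and
  protective genes fall across patterns.
* **Metabolic block.** Four categories with per-pattern activity
  profiles: lipid (1, 0.45, 0) — collapsing toward the top pattern;
  carbohydrate (1, 0.4, 0) — gradual decline; amino-acid (1, 0, 0.75)
  and other (1, 0.1, 0.6) — dipping at the intermediate pattern with
  partial recovery under the proliferative top pattern (glutamine and
  nucleotide demand rise with proliferation). All profiles start
  highest in pattern 1, so mean metabolic expression is negatively
  correlated with the pattern index while the pattern centroids stay
  non-collinear in pathway space. |`metabolic_coupling`| (default
  0.8) is the correlation between a category's pattern-determined
  activity and its realized activity; the implied noise SD is
  σ_c = sd(profile) · sqrt(1/ρ² − 1), of which one quarter (variance
  share) is common to all pathways of the category and the rest is
  pathway-specific. Expression loadings 1.5 / 1.2 / 1.0 / 1.0 (lipid /
  amino-acid / carbohydrate / other) make lipid the most altered
  category.
* **Gene sets.** 50 metabolic sets cycled over the four categories,
  sizes uniform in [10, 30], each 80% disjoint core genes plus 20%
  drawn from a 30-gene category pool (within-category Jaccard well
  below 0.3; an overlap of 0 gives fully disjoint sets). One
  `mRNA_methylation` set holds the 23 regulators plus 10 decoys.
* **Survival.** Exponential event times with log-hazard
  log(0.15) + cluster term (0, 0.3, 0.8) + 0.05 · (age − mean age)
  + 0.3 · stage level, censoring uniform on (0, 10) years. The age and
  stage terms are part of the design: in real HCC cohorts age and
  stage are independently prognostic, which is precisely why a
  nomogram combines them with the score. With a three-level hazard
  alone, any predictor — including the true pattern — caps the
  cumulative/dynamic AUC near 0.62 because risk would take only three
  values; the continuous age term removes that artificial ceiling.
  Exponential times with uniform censoring keep Cox parameter recovery
  checkable in closed form.
* **Clinical covariates.** Age ~ N(62 − 2z, 10) rounded and clipped to
  [18, 90] (higher-pattern tumors slightly younger); TNM stage
  probabilities interpolate from (0.45, 0.30, 0.18, 0.07) at pattern 1
  to (0.15, 0.25, 0.38, 0.22) at pattern 3; T stage is the TNM level
  jittered by ±1. Treatment response is Bernoulli per pattern
  (defaults 0.2 / 0.35 / 0.6 PR/SD), rising with the pattern index.

Setting `regulator_shift = 0` with zero cluster log-hazards yields a
null cohort with no pattern structure, used for calibration tests.

What the generator does **not** emulate: read-count noise models,
microarray probe effects, batch structure across cohorts, copy-number
or DNA-methylation layers, gene–gene correlation beyond the explicit
pattern and category factors, and non-proportional hazards. Passing
tests therefore demonstrate that the pipeline recovers the intended
structure under clean conditions; they do not certify performance on
real multi-platform cohorts, where batch correction (out of scope
here) and platform-specific preprocessing come first.

## Numerical and degenerate-input policies

Readers reject malformed inputs rather than coercing (duplicate
sample IDs, non-numeric cells with coordinates, short GMT lines with
line numbers); duplicate gene rows collapse to the highest-mean row;
genes with missing values are dropped before analysis with a logged
count; samples lacking survival information are excluded. Constant
genes scale to 0 in the m6Ascore and are excluded from the Cox screen.
Chi-square tests run without continuity correction by default (Yates
is available for 2×2); expected cell counts below 5 set a warning
flag. All stochastic steps take explicit seeds; identical
configuration and seed reproduce byte-identical outputs.

## Problem sizes

The bundled analyses run at n = 300 samples and 2000 genes with 20
replicate cohorts for cluster-number studies, 50 replicates for Cox
recovery (n = 1000), and 2000 replicates for log-rank calibration —
sizes at which every distributional claim the tests make is
well-resolved while a full suite completes in minutes on one CPU.
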