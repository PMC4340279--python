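# Methods

## Pipeline overview

Given a features × samples mRNA matrix, a parallel microRNA matrix measured
on the same subjects, binary case/control labels, one or more annotation
collections (GMT), a disease seed-gene list and a validated miRNA→gene
target map, the pipeline builds four types of pre-filtered dataset per
layer, runs L1-penalized logistic-regression feature selection on each, and
compares them on cross-validated AUC, precision, percent feature reduction,
selected-feature overlap and enriched-term coverage.

| Type | mRNA layer | microRNA layer |
|---|---|---|
| 1 | all features | all features |
| 2 | t-test p ≤ α_DE | t-test p ≤ α_DE |
| 3 | annotated to ≥1 term enriched in the seed genes (one dataset per collection) | ≥1 validated target among the seed genes |
| 4 | Type 2 ∩ Type 3 | Type 2 ∩ Type 3 |

Type 4 is formalized as the exact intersection of the Type-2 and Type-3
feature sets (computed with identical thresholds). The equivalent prose
definition — "differentially expressed features with disease-related
annotation" — is implied by this set algebra, and the intersection law
`type4 = type2 ∩ type3` is asserted in the tests. With the canonical four
collections (BP, MF, CC, Pathway) the mRNA layer yields 10 datasets and the
microRNA layer 4, i.e. 14 in total, in the fixed order type1, type2,
type3-{BP,MF,CC,Pathway}, type4-{BP,MF,CC,Pathway}.

Empty filter outcomes are representable: the dataset is built, logged with a
warning, and every downstream stage refuses it explicitly
(`EmptyDatasetError`); the pipeline turns it into a report row flagged
`skipped` with NaN metrics rather than dropping it.

## Statistical primitives

**Differential expression.** Two-sided two-sample t-test per feature.
Default is Welch's unequal-variance form (robust to the variance
heterogeneity typical of expression data); the classical Student form is
available via `equal_var=True`. Thresholds are inclusive (p ≤ α, default
α = 0.05). Degenerate features (zero variance in both classes) get p = 1
when the means are equal, and an infinite-statistic sentinel with p = 0
when they differ — with no within-class noise, any mean difference is
treated as certain.

**Enrichment.** For a gene list of size d against a term of size a in a
universe of size b with overlap n, the p-value is the inclusive upper tail
P(X ≥ n) of the hypergeometric distribution — the standard
over-representation convention; the strict tail is available via
`strict=True`. The universe (the test's background b) is always fixed
explicitly with `restrict_to_universe`, normally to the features present on
the array; terms emptied by the restriction are dropped. No multiple-testing
correction is applied by default, matching common first-pass practice for
this style of filter; Benjamini–Hochberg is available behind `correct=True`.
Computation delegates to `scipy.stats.hypergeom.sf` (log-space stable) and
is verified in the tests against an exact rational brute-force tail sum for
every valid argument combination with b ≤ 60 plus random cases up to
b ≤ 200, at relative error ≤ 1e−10.

One ambiguity in the source methodology: the text describes annotating both
the seed genes *and* all genes on the array "separately", but enriching the
full universe against itself is degenerate (every term gets p = 1, as our
tests assert). Only the seed-list enrichment is meaningful and implemented;
array genes enter as the universe.

## L1 logistic regression

The selection engine minimizes `F(w,b) = L(w,b) + λ‖w‖₁` with L the mean
Bernoulli negative log-likelihood under the logit link and the intercept
unpenalized.

* **Standardization.** Features are z-scored inside the solver (training
  folds only during CV) so one λ is commensurable across features; weights
  are reported back on the original scale. Constant features get scale 1 and
  stay at zero weight.
* **Solver.** Proximal gradient (ISTA) with backtracking line search and a
  monotone Nesterov acceleration: the extrapolated step is taken only when
  the penalized objective does not increase, so F is non-increasing across
  iterations by construction. Because first-order methods close the last
  digits of optimality slowly, an active-set damped-Newton polish runs
  periodically: with the support and signs frozen the problem is smooth, and
  Newton steps (sign-crossing coordinates clipped to exactly zero, steps
  accepted only on objective decrease, or on a ≥2× active-gradient-norm
  decrease when the objective is flat at float64 resolution) finish
  convergence quadratically.
* **Convergence** is declared on the KKT residual
  `max(|∂L/∂b|, max_{w_j=0} (|∂L/∂w_j|−λ)₊, max_{w_j≠0} |∂L/∂w_j + λ sign w_j|) ≤ tol`
  (default 1e−6). Tolerances much below ~1e−9 are not certifiable in double
  precision for this objective and should not be requested.
* **λ selection.** `λ_max = max_j |∂L/∂w_j|` at w = 0, b = logit(prevalence)
  is the smallest penalty with an all-zero optimum (asserted exactly in
  tests). The default strategy evaluates a 50-point log grid on
  [λ_max·10⁻³, λ_max] by stratified inner 5-fold CV on held-out log-loss,
  warm-starting down the path, breaking ties toward the larger (sparser) λ,
  then refits once on all samples; the selected features are those with
  |w_j| > 1e−9 after back-transformation. A fixed-λ strategy is available.
  The reported feature set always comes from the single full-data fit;
  per-fold fits are used only for performance metrics.

The λ = 0 case reproduces an independent Newton maximum-likelihood oracle to
1e−6 per coefficient, and penalized fits are cross-checked against
scikit-learn's saga solver (used as an oracle only; the in-repo solver is
the implementation).

## Evaluation

* **Cross-validation** is stratified k-fold (default k = 5), seeded and
  deterministic. Stratification is a deliberate deviation from plain k-fold:
  with heavily imbalanced cohorts (e.g. 106 cases vs 20 controls),
  unstratified folds risk single-class test folds in which AUC is undefined.
  When a class has fewer than k members the splitter falls back to
  unstratified folds with a warning. Held-out scores are pooled across folds
  for the reported AUC/precision (per-fold values are kept alongside);
  pooling is the primary aggregation because a single score vector scores
  every sample exactly once.
* **AUC** is the rank-based estimator with ties counted ½, which equals the
  exhaustive positive-negative pair comparison (property-tested on random
  vectors with ties).
* **Precision** is TP/(TP+FP) calling positive at probability ≥ 0.5
  (positive class = disease). When no sample is called positive the metric
  is undefined and reported as NaN, never as 0.
* **Percent reduction** is 100·(raw − kept)/raw.
* **Overlap analysis** reports pairwise intersection counts, the occurrence
  histogram and the features selected in ≥2 datasets per layer.
* **Term coverage** of a selection is |E_sel ∩ E_seed| / |E_seed| where E_x
  is the set of terms enriched (p ≤ α) in gene list x. This implements the
  *enrichment* reading of "selected genes enriched in X% of the seed genes'
  enriched terms"; a mere annotation-overlap reading would be cheaper but
  does not follow from the stated enrichment machinery.
* **Computing time** is measured per CV run and reported informationally; it
  is hardware-dependent and excluded from every assertion.

## Synthetic studies

`simulate_study` generates a paired two-class study with ground truth:

* Expression: feature f has baseline μ_f ~ Normal(7, 2²) (log2-intensity
  scale) and unit within-class variance; a fraction `frac_de` of features is
  planted with an additive `effect_size`·SD shift in the positive class.
  This is the simplest model satisfying the t-filter's assumptions — which
  is exactly the structure the filter presumes.
* Seed genes are drawn from the planted set with probability
  `seed_enrichment_bias` (default 0.9); disease terms draw ≥
  `disease_member_frac` (default 0.8) of members from seed ∪ planted genes,
  background terms draw uniformly; target pairs link planted miRNAs to seed
  genes with probability `target_bias` (default 0.8).
* Defaults are the test scale: 30+30 samples, 500 genes, 60 miRNAs, four
  20-term collections, 40 seed genes, effect size 1.5 — the full pipeline
  runs in seconds. `full_scale_config()` reproduces the dimensions of a
  real paired hypertrophic-cardiomyopathy cohort (106/20 samples, 18756
  genes, 819 miRNAs, 372 seed genes, 5140/2782/851/2999 terms, 19550 target
  pairs) for scale testing.
* All draws come from a single `default_rng(rng_seed)` stream in a fixed
  documented order; studies are bit-reproducible from the config.

What the generator does *not* emulate: probe-level structure, dye/batch
effects, correlated co-expression blocks, heavy-tailed noise, missing
values. A green pipeline on synthetic data therefore establishes
correctness of the filtering/selection/evaluation machinery and its
calibration under the stated Gaussian world — not performance claims about
any real cohort.

## Reproducibility

A single top-level pipeline seed derives the simulation, fold and solver
seeds through `numpy.random.SeedSequence.spawn` in that fixed order; two
runs with the same configuration and seed produce identical reports up to
wall-clock timings (asserted in tests).

## Numerical and degenerate-input choices

* Matrix writes use 6-significant-digit formatting (`%.6g`), documented so
  round-trip tests are bit-exact for representable values.
* IDs are case-sensitive opaque strings; no symbol normalization.
* Expression values are used as given — no normalization stage is applied.
* Probe collapse (when a probe→gene map is supplied) takes the per-sample
  mean across a gene's probes by default (median via `rule="median"`); a
  probe mapping to two genes is refused rather than guessed.
* Enrichment output ordering is total and deterministic: p-value, then
  lexicographic term ID.
* `percent_reduction` rejects raw_count = 0; AUC and precision raise an
  explicit undefined-metric error when a class is absent.

## Known limitations

* Only binary designs are supported (no ANOVA/multiclass path).
* No predicted (non-validated) miRNA targets; the target map is taken as
  validated pairs.
* No GEO/series-matrix ingestion; all inputs are local flat files.
* The L1 path offers no elastic-net or group penalties.
* Published percent-reduction figures from the motivating comparison are
  reproduced from their printed counts in the test suite; one printed value
  (mRNA Type-3 MF, 40.58%) disagrees with its own printed counts, which give
  40.56% — the recomputed value is the one asserted.
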