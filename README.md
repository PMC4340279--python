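# prefilterfs

Comparative benchmarking of **pre-filter methods for feature selection** on
paired mRNA / microRNA expression studies.

## The problem

Microarray (and other omics) studies typically measure tens of thousands of
features on a few dozen samples. Embedded feature-selection methods such as
L1-penalized logistic regression handle that regime, but become slow and
unstable as the feature count grows, so practitioners *pre-filter* the matrix
first, using either

* **statistical knowledge** — keep only differentially expressed features
  (two-sample t-test, p ≤ 0.05), or
* **biological knowledge** — keep only features that share an enriched
  annotation term (GO BP/MF/CC, pathways; hypergeometric test, p ≤ 0.05) with
  a list of validated disease genes, or, for microRNAs, that have a validated
  target among those disease genes, or
* **both combined**.

This package implements that comparison as a reusable pipeline. For an mRNA
layer it constructs ten datasets — Type 1 (raw), Type 2 (t-filtered),
Type 3-{BP,MF,CC,Pathway} (enrichment-filtered) and Type 4-{…} (the
intersection of Types 2 and 3) — and for a microRNA layer the four analogues
(Type 3 uses a validated miRNA→gene target map instead of enrichment). Each
dataset is then run through L1-logistic feature selection and scored by
stratified 5-fold cross-validated AUC and precision, percent feature
reduction, the overlap of selected features across datasets, and the
coverage of the disease genes' enriched terms by the selected genes.

## The core model

Feature selection solves

```
min_{w,b}  L(w, b) + λ‖w‖₁ ,
L(w, b) = (1/N) Σₙ [ log(1 + exp(wᵀxₙ + b)) − yₙ (wᵀxₙ + b) ]
```

with samples xₙ ∈ R^p, binary labels yₙ ∈ {0,1} (1 = disease) and an
unpenalized intercept b. Features with nonzero ŵⱼ are the selected features.
λ is chosen on a log grid below λ_max = max_j |∂L/∂w_j|(0, b₀) by inner
stratified cross-validation on held-out log-loss. Enrichment uses the
upper-tail hypergeometric probability P(X ≥ n) with population b (the
universe), successes a (term size), draws d (list size) and overlap n. AUC
is the Mann–Whitney rank estimator (ties count ½); precision is TP/(TP+FP)
at probability threshold 0.5.

Because the original cohort data are not redistributable, the package ships
a synthetic-study generator (`prefilterfs.synthetic`) that emulates a paired
case/control design — Gaussian log-intensities with a planted mean shift in
a fraction of features, disease seed genes biased toward the planted set,
annotation collections with disease terms built from them, and a target map
linking planted miRNAs to seed genes — with full ground truth, so every
claim the pipeline makes is testable.

## Worked example

```python
from prefilterfs import PipelineConfig, SolverConfig, run_pipeline
from prefilterfs.synthetic import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(),          # 30+30 samples, 500 genes, 60 miRNAs
    solver=SolverConfig(lambda_grid_size=20),
    seed=1,
)
report = run_pipeline(config)
for r in report.rows:
    print(r.layer, r.tag, r.raw_variables, r.kept_features, r.selected_features,
          round(r.percent_reduction, 2), round(r.auc, 3))
```

prints (elapsed columns omitted):

```
dataset            raw  kept selected reduction%    AUC precision
mRNA/type1         500   500       28       0.00  1.000     1.000
mRNA/type2         500    70       28      86.00  1.000     1.000
mRNA/type3-BP      500    59       26      88.20  1.000     1.000
mRNA/type3-MF      500    58       25      88.40  0.999     0.967
mRNA/type3-CC      500    60       24      88.00  1.000     1.000
mRNA/type3-Pathway 500    55       22      89.00  1.000     1.000
mRNA/type4-BP      500    43       26      91.40  1.000     1.000
mRNA/type4-MF      500    37       25      92.60  0.999     0.967
mRNA/type4-CC      500    44       24      91.20  1.000     1.000
mRNA/type4-Pathway 500    36       22      92.80  1.000     1.000
miRNA/type1         60    60       19       0.00  0.967     0.875
miRNA/type2         60     6        6      90.00  0.981     0.931
miRNA/type3         60     6        6      90.00  0.981     0.931
miRNA/type4         60     6        6      90.00  0.981     0.931
```

Reading the table: the t-filter (type2) removed 86% of the synthetic genes
while classification stayed perfect — the planted signal survives the
pre-filter — and the combined filters (type4) removed up to ~93% with no
loss. On this run 42 mRNA features recur in at least two selections, and the
genes kept by the BP enrichment filter cover 100% of the seed genes'
enriched BP terms (`report.coverage["type3-BP"]["BP"]`). On real cohorts the
gains are smaller; the synthetic world's planted effect (1.5 SD) is
deliberately strong so that recovery failures indicate bugs, not noise.

A CLI mirrors the library: `prefilterfs simulate | build-datasets | select |
evaluate | run` (see `prefilterfs --help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch at the default synthetic scale —
simulation, the 14 dataset constructions, per-dataset L1 selection and
5-fold cross-validated evaluation — and writes its target values as JSON.

## Layout

* `prefilterfs.io_model` — data model (expression matrix, labels, gene-set
  collections, target map, filtered datasets) and all TSV/GMT readers/writers
* `prefilterfs.stat_tests` — two-sample t-test, hypergeometric enrichment
* `prefilterfs.dataset_builder` — the Type 1–4 constructions for both layers
* `prefilterfs.l1_logistic` — the in-repo L1 logistic solver, λ path, selection
* `prefilterfs.evaluation` — stratified CV, AUC, precision, reductions,
  overlap, term coverage
* `prefilterfs.synthetic` — the synthetic-study generator
* `prefilterfs.pipeline` / `prefilterfs.cli` — orchestration and reporting

See `docs/methods.md` for the modelling and numerical details.
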