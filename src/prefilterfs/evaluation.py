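"""Benchmarking of the pre-filter + selection pipeline.

Measures per dataset: cross-validated AUC and precision (plus wall-clock
time, reported informationally), the percent feature reduction relative to
the raw dataset, the overlap structure of selected-feature sets across
datasets, and the enriched-term coverage of a selection relative to the
disease seed genes.

Cross-validation is stratified k-fold (the heavy class imbalance of
case/control cohorts makes unstratified folds risk single-class folds);
held-out scores from all folds are pooled before computing AUC and
precision, and per-fold metrics are reported alongside. AUC uses the
rank-based (Mann-Whitney) estimator with ties counted one half — the
probability that a random positive is scored above a random negative.
Precision is TP/(TP+FP) at a fixed probability threshold (default 0.5);
when no sample is called positive, precision is undefined and reported as
NaN, never silently zero.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateLabelsError, EmptyDatasetError, UndefinedMetricError
from .io_model import AnnotationCollection, FilteredDataset, SampleLabels
from .l1_logistic import (
    SelectionResult,
    SolverConfig,
    fit_l1_logistic,
    lambda_grid,
    _mean_heldout_logloss,
)
from .stat_tests import enrich

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class FoldMetrics:
    fold: int
    auc: float
    precision: float
    n_test: int


@dataclass(frozen=True)
class CVResult:
    """Pooled cross-validation outcome for one dataset."""

    fold_assignments: np.ndarray
    pooled_scores: np.ndarray  # one held-out probability per sample
    auc: float
    precision: float
    confusion: ConfusionCounts
    elapsed_seconds: float
    per_fold: tuple[FoldMetrics, ...]


@dataclass(frozen=True)
class OverlapReport:
    """Cross-dataset structure of the selected-feature sets."""

    tags: tuple[str, ...]
    pairwise_counts: np.ndarray  # symmetric |S_i ∩ S_j| matrix
    occurrences: dict[str, int]  # feature -> number of selections containing it
    recurrent_features: tuple[str, ...]  # features appearing >= 2 times, sorted


def stratified_kfold(labels: SampleLabels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Folds are sized within one of each other and preserve the class
    proportions to within one sample per fold. Falls back to plain k-fold
    with a warning when a class has fewer than k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = labels.labels
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    if np.min(np.bincount(y)) < k:
        logger.warning("a class has < %d members; falling back to unstratified folds", k)
        idx = rng.permutation(n)
        assign[idx] = np.arange(n) % k
        return assign
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % k
    return assign


def auc(scores, labels) -> float:
    """Rank-based AUC with ties counted one half.

    Equals exhaustive comparison of every positive-negative pair:
    (wins + 0.5 * ties) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    y = labels.labels if isinstance(labels, SampleLabels) else np.asarray(labels)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC requires both classes present")
    ranks = stats.rankdata(scores)  # average ranks handle ties as half-wins
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def precision_at_threshold(
    scores, labels, threshold: float = 0.5
) -> tuple[float, ConfusionCounts]:
    """Precision TP/(TP+FP) calling positive iff score >= threshold.

    Returns (NaN, counts) when nothing is called positive — the metric is
    undefined there and must be reported as such.
    """
    scores = np.asarray(scores, dtype=float)
    y = labels.labels if isinstance(labels, SampleLabels) else np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("precision requires both classes present")
    called = scores >= threshold
    counts = ConfusionCounts(
        TP=int(np.sum(called & (y == 1))),
        FP=int(np.sum(called & (y == 0))),
        TN=int(np.sum(~called & (y == 0))),
        FN=int(np.sum(~called & (y == 1))),
    )
    if counts.TP + counts.FP == 0:
        logger.warning("no sample called positive at threshold %g; precision undefined", threshold)
        return float("nan"), counts
    return counts.TP / (counts.TP + counts.FP), counts


def cross_validate(
    ds: FilteredDataset,
    solver: SolverConfig | None = None,
    k: int = 5,
    seed: int = 0,
    strategy: str = "inner-cv",
    threshold: float = 0.5,
) -> CVResult:
    """Stratified k-fold evaluation of the L1 model on one dataset.

    Per fold, lambda is chosen within the training folds only (by the
    configured strategy), the model is fit there, and the held-out fold is
    scored; all held-out scores are pooled for the reported AUC and
    precision. Wall time covers all fits and is hardware-dependent.
    """
    solver = solver or SolverConfig()
    if ds.is_empty:
        raise EmptyDatasetError(f"dataset {ds.tag} is empty; refusing to cross-validate")
    y = ds.labels.aligned_to(ds.matrix.sample_ids)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError(f"dataset {ds.tag} has a single class")
    X = ds.matrix.values.T
    folds = stratified_kfold(
        SampleLabels(ds.matrix.sample_ids, y), k, seed
    )
    pooled = np.full(len(y), np.nan)
    per_fold = []
    t0 = time.perf_counter()
    for f in range(k):
        tr, te = folds != f, folds == f
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            raise DegenerateLabelsError(f"fold {f} of {ds.tag} has a single class")
        if strategy == "fixed":
            if solver.lambda_ is None:
                raise ValueError("fixed strategy requires solver.lambda_")
            lam = solver.lambda_
        else:
            grid = lambda_grid(X[tr], y[tr], solver)
            mean_loss = _mean_heldout_logloss(X[tr], y[tr], grid, solver)
            lam = float(np.asarray(sorted(grid, reverse=True))[int(np.argmin(mean_loss))])
        fit = fit_l1_logistic(X[tr], y[tr], solver, lambda_=lam)
        scores_te = fit.predict_proba(X[te])
        pooled[te] = scores_te
        fold_auc = auc(scores_te, y[te])
        fold_prec, _ = precision_at_threshold(scores_te, y[te], threshold)
        per_fold.append(FoldMetrics(f, fold_auc, fold_prec, int(te.sum())))
    elapsed = time.perf_counter() - t0
    assert not np.isnan(pooled).any()  # every sample scored exactly once
    pooled_auc = auc(pooled, y)
    pooled_prec, confusion = precision_at_threshold(pooled, y, threshold)
    return CVResult(
        fold_assignments=folds,
        pooled_scores=pooled,
        auc=pooled_auc,
        precision=pooled_prec,
        confusion=confusion,
        elapsed_seconds=elapsed,
        per_fold=tuple(per_fold),
    )


def percent_reduction(raw_count: int, kept_count: int) -> float:
    """Percentage of features removed relative to the raw dataset:
    100 * (raw - kept) / raw."""
    if raw_count <= 0:
        raise ValueError("raw_count must be > 0")
    if not 0 <= kept_count <= raw_count:
        raise ValueError("kept_count must satisfy 0 <= kept <= raw")
    return 100.0 * (raw_count - kept_count) / raw_count


def overlap_analysis(selections: list[SelectionResult]) -> OverlapReport:
    """Pairwise intersections and the occurrence histogram across selections.

    ``recurrent_features`` are features selected in at least two datasets,
    sorted by descending occurrence count then feature ID.
    """
    if len(selections) < 2:
        raise ValueError("overlap analysis needs >= 2 selections")
    tags = tuple(s.tag for s in selections)
    sets = [s.feature_set for s in selections]
    m = len(sets)
    counts = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(m):
            counts[i, j] = len(sets[i] & sets[j])
    occurrences: dict[str, int] = {}
    for s in sets:
        for feat in s:
            occurrences[feat] = occurrences.get(feat, 0) + 1
    recurrent = tuple(
        sorted((f for f, c in occurrences.items() if c >= 2), key=lambda f: (-occurrences[f], f))
    )
    return OverlapReport(tags, counts, occurrences, recurrent)


def term_coverage(
    selected_genes,
    seed_genes,
    coll: AnnotationCollection,
    alpha: float = 0.05,
) -> float:
    """Fraction of the seed genes' enriched terms also enriched in the
    selected genes: |E_seed ∩ E_selected| / |E_seed|.

    Returns NaN (undefined) when the seed list enriches no term.
    """
    e_seed = {t.term_id for t in enrich(seed_genes, coll, alpha)}
    if not e_seed:
        logger.warning("seed genes enrich no %s term; coverage undefined", coll.collection_name)
        return float("nan")
    e_sel = {t.term_id for t in enrich(selected_genes, coll, alpha)}
    return len(e_seed & e_sel) / len(e_seed)
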