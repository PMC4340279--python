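"""The two statistical primitives behind the pre-filters.

* ``two_sample_t`` — two-sided two-sample t-test (Welch by default, Student
  equal-variance via ``equal_var=True``). Degenerate inputs where both
  groups are constant with equal means return statistic 0 and p = 1 by
  convention; constant groups with unequal means return an infinite
  statistic sentinel and p = 0.

* ``hypergeom_pvalue`` / ``enrich`` — over-representation of a gene list in
  annotation terms via the upper-tail inclusive hypergeometric probability
  P(X >= n), with parameters named after the field convention: ``a`` = term
  size in the universe, ``b`` = universe size, ``d`` = list size, ``n`` =
  list-term intersection size. Thresholds are inclusive (p <= alpha). No
  multiple-testing correction is applied by default; Benjamini-Hochberg is
  available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError
from .io_model import AnnotationCollection, SampleLabels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    feature_id: str
    statistic: float
    p_value: float


@dataclass(frozen=True)
class EnrichedTerm:
    """One hypergeometric test outcome for a term against a gene list."""

    term_id: str
    a: int  # term size within the universe
    b: int  # universe size
    d: int  # gene-list size
    n: int  # |list ∩ term|
    p_value: float


def two_sample_t(
    values,
    labels: SampleLabels | np.ndarray,
    feature_id: str = "",
    equal_var: bool = False,
) -> TestResult:
    """Two-sided two-sample t-test of one feature between the two classes.

    Welch's unequal-variance form is the default; pass ``equal_var=True``
    for the classical Student form. Requires >= 2 samples per class.
    """
    values = np.asarray(values, dtype=float)
    y = labels.labels if isinstance(labels, SampleLabels) else np.asarray(labels)
    pos, neg = values[y == 1], values[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError(
            f"t-test needs >=2 samples per class, got {len(pos)}/{len(neg)}"
        )
    if np.var(pos) == 0.0 and np.var(neg) == 0.0:
        # zero variance in both classes: no sampling noise, so equal means
        # are maximally null and unequal means maximally non-null
        if np.mean(pos) == np.mean(neg):
            return TestResult(feature_id, 0.0, 1.0)
        sentinel = math.inf if np.mean(pos) > np.mean(neg) else -math.inf
        return TestResult(feature_id, sentinel, 0.0)
    stat, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return TestResult(feature_id, float(stat), float(p))


def t_test_matrix(
    values: np.ndarray, y: np.ndarray, equal_var: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row t-test for a features x samples matrix.

    Returns (statistics, two-sided p-values); degenerate rows follow the
    same conventions as :func:`two_sample_t`.
    """
    pos, neg = values[:, y == 1], values[:, y == 0]
    if pos.shape[1] < 2 or neg.shape[1] < 2:
        raise InsufficientDataError("t-test needs >=2 samples per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(pos, neg, axis=1, equal_var=equal_var)
    stat, p = np.asarray(stat, dtype=float), np.asarray(p, dtype=float)
    degen = (np.var(pos, axis=1) == 0.0) & (np.var(neg, axis=1) == 0.0)
    if degen.any():
        dm = pos[degen].mean(axis=1) - neg[degen].mean(axis=1)
        stat[degen] = np.where(dm == 0, 0.0, np.where(dm > 0, np.inf, -np.inf))
        p[degen] = np.where(dm == 0, 1.0, 0.0)
    return stat, p


def hypergeom_pvalue(a: int, b: int, d: int, n: int, strict: bool = False) -> float:
    """Upper-tail hypergeometric probability for over-representation.

    For X ~ Hypergeometric(population ``b``, successes ``a``, draws ``d``),
    returns the inclusive tail P(X >= n) (the strict tail P(X > n) with
    ``strict=True``). Computed via scipy's survival function, which works in
    log space and is stable for large arguments.
    """
    if not (0 <= n <= min(a, d) and 0 <= a <= b and 0 <= d <= b):
        raise ValueError(f"invalid hypergeometric arguments a={a}, b={b}, d={d}, n={n}")
    k = n if strict else n - 1
    return float(stats.hypergeom.sf(k, b, a, d))


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich(
    gene_list,
    coll: AnnotationCollection,
    alpha: float = 0.05,
    correct: bool = False,
) -> list[EnrichedTerm]:
    """Hypergeometric over-representation of ``gene_list`` in each term.

    Genes outside the collection's universe are dropped with a logged count.
    Returns terms with p <= ``alpha`` (on BH-adjusted p-values when
    ``correct``), sorted by p-value then term ID.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    genes = set(gene_list)
    kept = genes & coll.universe
    if len(kept) < len(genes):
        logger.warning(
            "enrich: dropped %d gene(s) outside the %s universe",
            len(genes) - len(kept),
            coll.collection_name,
        )
    if not kept:
        logger.warning("enrich: empty gene list after universe restriction")
        return []
    b, d = len(coll.universe), len(kept)
    results = []
    for term_id, members in coll.terms.items():
        a = len(members & coll.universe)
        n = len(kept & members)
        results.append(
            EnrichedTerm(term_id, a, b, d, n, hypergeom_pvalue(a, b, d, n))
        )
    if correct and results:
        adjusted = benjamini_hochberg(np.array([r.p_value for r in results]))
        results = [
            EnrichedTerm(r.term_id, r.a, r.b, r.d, r.n, float(q))
            for r, q in zip(results, adjusted)
        ]
    enriched = [r for r in results if r.p_value <= alpha]
    enriched.sort(key=lambda r: (r.p_value, r.term_id))
    return enriched
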