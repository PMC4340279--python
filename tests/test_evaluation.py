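import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefilterfs import (
    SolverConfig,
    auc,
    cross_validate,
    overlap_analysis,
    percent_reduction,
    precision_at_threshold,
    stratified_kfold,
    term_coverage,
)
from prefilterfs.dataset_builder import build_type1, build_type2
from prefilterfs.errors import UndefinedMetricError
from prefilterfs.io_model import SampleLabels
from prefilterfs.l1_logistic import SelectionResult
from prefilterfs.synthetic import SimulationConfig, simulate_study


def auc_pairwise_oracle(scores, y):
    """Exhaustive positive-negative pair comparison, ties counted one half."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _selection(tag, features):
    dtype, _, variant = tag.partition("-")
    return SelectionResult(dtype, variant or None, tuple(features),
                           tuple(1.0 for _ in features), 0.1, fit=None)


class TestStratifiedKFold:
    def test_each_fold_has_both_classes(self, small_labels):
        # 10 samples (6/4): with k=4 every fold can and must see both classes
        folds = stratified_kfold(small_labels, k=4, seed=0)
        for f in range(4):
            ys = small_labels.labels[folds == f]
            assert set(ys) == {0, 1}

    def test_deterministic_given_seed(self, small_labels):
        a = stratified_kfold(small_labels, k=5, seed=42)
        b = stratified_kfold(small_labels, k=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_partition_law(self, small_labels):
        folds = stratified_kfold(small_labels, k=3, seed=1)
        assert len(folds) == small_labels.n_samples
        assert set(folds) == {0, 1, 2}
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 1

    def test_k_larger_than_n_rejected(self, small_labels):
        with pytest.raises(ValueError):
            stratified_kfold(small_labels, k=11, seed=0)

    def test_fallback_when_class_smaller_than_k(self):
        labels = SampleLabels(tuple(f"S{i}" for i in range(8)),
                              np.array([1, 0, 0, 0, 0, 0, 0, 0]))
        folds = stratified_kfold(labels, k=4, seed=0)
        assert set(folds) == {0, 1, 2, 3}


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_is_half(self):
        assert auc([0.5] * 6, np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_enumerated_example(self):
        # pairs: .35 vs {.1 win, .4 loss}; .8 vs {.1, .4} both wins -> 3/4
        assert auc([0.1, 0.4, 0.35, 0.8], np.array([0, 0, 1, 1])) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.2], np.array([1, 1]))

    @given(
        n=st.integers(4, 60),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_exhaustive_pairwise_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        # coarse grid forces plenty of ties
        scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert auc(scores, y) == pytest.approx(auc_pairwise_oracle(scores, y), abs=1e-12)

    def test_flip_symmetry(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(size=30)
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        assert auc(1 - scores, 1 - y) == pytest.approx(auc(scores, y), abs=1e-12)


class TestPrecision:
    def test_counts_forced_by_formula(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01])
        y = np.array([1, 1, 1, 0, 0, 1, 0, 0, 1, 0])
        prec, counts = precision_at_threshold(scores, y, threshold=0.5)
        assert (counts.TP, counts.FP) == (3, 1)
        assert prec == pytest.approx(0.75)
        assert counts.total == 10

    def test_no_false_positives(self):
        prec, _ = precision_at_threshold([0.9, 0.8, 0.1], np.array([1, 1, 0]), 0.5)
        assert prec == 1.0

    def test_nothing_called_positive_is_nan(self):
        prec, counts = precision_at_threshold([0.1, 0.2, 0.3], np.array([1, 0, 1]), 0.5)
        assert math.isnan(prec)
        assert counts.TP + counts.FP == 0

    def test_threshold_zero_gives_prevalence(self):
        y = np.array([1, 1, 0, 0, 0])
        prec, _ = precision_at_threshold([0.5] * 5, y, threshold=0.0)
        assert prec == pytest.approx(y.mean())


class TestPercentReduction:
    @pytest.mark.parametrize(
        "raw,kept,expected",
        [
            (18756, 3604, 80.78),
            (819, 114, 86.08),
            (100, 100, 0.0),
        ],
    )
    def test_examples(self, raw, kept, expected):
        assert percent_reduction(raw, kept) == pytest.approx(expected, abs=0.005)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            percent_reduction(0, 0)
        with pytest.raises(ValueError):
            percent_reduction(5, 6)


class TestOverlapAnalysis:
    def test_counting_example(self):
        report = overlap_analysis([
            _selection("type1", ["a", "b", "c"]),
            _selection("type2", ["b", "c"]),
            _selection("type3-BP", ["c"]),
        ])
        assert set(report.recurrent_features) == {"b", "c"}
        assert report.occurrences == {"a": 1, "b": 2, "c": 3}
        assert report.recurrent_features[0] == "c"  # sorted by occurrence desc
        np.testing.assert_array_equal(report.pairwise_counts,
                                      [[3, 2, 1], [2, 2, 1], [1, 1, 1]])
        np.testing.assert_array_equal(report.pairwise_counts,
                                      report.pairwise_counts.T)

    def test_identical_sets(self):
        sels = [_selection(f"type{i}", ["x", "y"]) for i in (1, 2)]
        report = overlap_analysis(sels)
        assert report.pairwise_counts.tolist() == [[2, 2], [2, 2]]

    def test_disjoint_sets_no_recurrent(self):
        report = overlap_analysis([_selection("type1", ["a"]), _selection("type2", ["b"])])
        assert report.recurrent_features == ()

    def test_needs_two_selections(self):
        with pytest.raises(ValueError):
            overlap_analysis([_selection("type1", ["a"])])


class TestTermCoverage:
    def test_identical_inputs_full_coverage(self, hand_collection):
        seed = {"g1", "g2", "g3", "g4"}
        assert term_coverage(seed, seed, hand_collection) == 1.0

    def test_disjoint_enrichment_zero(self, hand_collection):
        seed = {"g1", "g2", "g3", "g4"}  # enriches D
        selected = {"g15", "g16", "g17"}  # annotated nowhere
        assert term_coverage(selected, seed, hand_collection) == 0.0

    def test_partial_coverage_hand_computed(self):
        """20-gene universe, 3 seed-enriched terms, selection covering 2."""
        from prefilterfs.io_model import AnnotationCollection

        universe = frozenset(f"g{i}" for i in range(1, 21))
        coll = AnnotationCollection("BP", {
            "T1": frozenset({"g1", "g2", "g3"}),
            "T2": frozenset({"g2", "g3", "g4"}),
            "T3": frozenset({"g1", "g4", "g5"}),
            "BG": frozenset({"g10", "g11", "g12", "g13", "g14", "g15"}),
        }, universe)
        # brute-force tail: a=3, b=20, d=5, n=3 -> p = C(17,2)/C(20,5) ≈ 0.0088;
        # a=3, d=4, n=3 -> 17/4845 ≈ 0.0035; n=2 of a=3, d=4 -> 425/4845 ≈ 0.088
        seed = {"g1", "g2", "g3", "g4", "g5"}  # enriches T1, T2, T3; not BG
        sel = {"g1", "g2", "g3", "g4"}  # fully contains T1, T2; only 2/3 of T3
        assert term_coverage(sel, seed, coll) == pytest.approx(2 / 3)

    def test_seed_enriching_nothing_is_nan(self, hand_collection):
        assert math.isnan(term_coverage({"g1"}, {"g15", "g16"}, hand_collection))


class TestCrossValidate:
    def test_every_sample_scored_once_and_informative_auc(self, fast_study):
        ds = build_type2(fast_study.mrna, fast_study.labels)
        cv = cross_validate(ds, SolverConfig(lambda_grid_size=10), k=5, seed=0)
        assert len(cv.pooled_scores) == fast_study.labels.n_samples
        assert np.all(np.isfinite(cv.pooled_scores))
        assert cv.auc >= 0.9  # strong planted signal
        assert len(cv.per_fold) == 5
        assert cv.confusion.total == fast_study.labels.n_samples

    def test_sample_order_invariance(self, fast_study):
        ds = build_type1(fast_study.mrna, fast_study.labels)
        config = SolverConfig(lambda_grid_size=8, seed=5)
        cv1 = cross_validate(ds, config, k=5, seed=3)
        cv2 = cross_validate(ds, config, k=5, seed=3)
        assert cv1.auc == cv2.auc and cv1.precision == cv2.precision
        np.testing.assert_array_equal(cv1.pooled_scores, cv2.pooled_scores)

    def test_null_study_auc_near_half(self):
        aucs = []
        for seed in range(6):
            cfg = SimulationConfig(n_genes=60, n_mirnas=10, effect_size=0.0,
                                   n_seed_genes=5, n_target_pairs=10,
                                   collection_specs=(("BP", 5),), rng_seed=seed)
            study = simulate_study(cfg)
            ds = build_type1(study.mrna, study.labels)
            cv = cross_validate(ds, SolverConfig(lambda_grid_size=8, seed=seed),
                                k=5, seed=seed)
            aucs.append(cv.auc)
        assert abs(float(np.median(aucs)) - 0.5) <= 0.12
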