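import numpy as np
import pytest
from scipy import stats

from prefilterfs import (
    BuildConfig,
    TargetMap,
    build_all,
    build_type1,
    build_type2,
    build_type3_mirna,
    build_type3_mrna,
    build_type4_mirna,
    build_type4_mrna,
)
from prefilterfs.io_model import ExpressionMatrix, SampleLabels
from prefilterfs.synthetic import SimulationConfig, simulate_study


def scipy_de_oracle(expr, labels, alpha):
    """Independent per-feature Welch t-test filter."""
    y = labels.aligned_to(expr.sample_ids)
    kept = []
    for i, f in enumerate(expr.feature_ids):
        _, p = stats.ttest_ind(expr.values[i, y == 1], expr.values[i, y == 0], equal_var=False)
        if p <= alpha:
            kept.append(f)
    return frozenset(kept)


class TestType1:
    def test_identity_filter(self, fast_study):
        ds = build_type1(fast_study.mrna, fast_study.labels)
        assert ds.feature_set == set(fast_study.mrna.feature_ids)
        assert ds.matrix.feature_ids == fast_study.mrna.feature_ids  # order preserved
        assert str(fast_study.mrna.n_features) in ds.provenance[0]


class TestType2:
    def test_matches_independent_oracle(self, fast_study):
        ds = build_type2(fast_study.mrna, fast_study.labels, alpha_de=0.05)
        assert ds.feature_set == scipy_de_oracle(fast_study.mrna, fast_study.labels, 0.05)

    def test_vacuous_threshold_keeps_everything(self, fast_study):
        ds = build_type2(fast_study.mrna, fast_study.labels, alpha_de=1.0)
        assert ds.feature_set == set(fast_study.mrna.feature_ids)

    def test_null_study_retention_near_alpha(self):
        cfg = SimulationConfig(n_genes=4000, n_mirnas=10, effect_size=0.0,
                               n_seed_genes=5, n_target_pairs=10,
                               collection_specs=(("BP", 5),), rng_seed=9)
        study = simulate_study(cfg)
        ds = build_type2(study.mrna, study.labels, alpha_de=0.05)
        frac = ds.matrix.n_features / study.mrna.n_features
        assert 0.035 <= frac <= 0.065

    def test_monotone_in_alpha(self, fast_study):
        sets = [
            build_type2(fast_study.mrna, fast_study.labels, alpha_de=a).feature_set
            for a in (0.01, 0.05, 0.2, 1.0)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestType3Mrna:
    def test_hand_fixture_recovers_disease_term(self, hand_collection):
        # one disease-like term D={g1..g5}; seed {g1,g2,g3,g4} makes D enriched
        rng = np.random.default_rng(0)
        features = tuple(sorted(hand_collection.universe))
        expr = ExpressionMatrix(features, tuple(f"S{i}" for i in range(8)),
                                rng.normal(size=(20, 8)))
        labels = SampleLabels(expr.sample_ids, np.array([1] * 4 + [0] * 4))
        ds = build_type3_mrna(expr, labels, hand_collection,
                              seed_genes={"g1", "g2", "g3", "g4"}, alpha_enrich=0.05)
        assert ds.feature_set == hand_collection.terms["D"]
        assert ds.variant == "BP"

    def test_no_seed_overlap_gives_empty(self, hand_collection):
        rng = np.random.default_rng(1)
        features = tuple(sorted(hand_collection.universe))
        expr = ExpressionMatrix(features, tuple(f"S{i}" for i in range(6)),
                                rng.normal(size=(20, 6)))
        labels = SampleLabels(expr.sample_ids, np.array([1, 1, 1, 0, 0, 0]))
        ds = build_type3_mrna(expr, labels, hand_collection,
                              seed_genes={"zz"}, alpha_enrich=0.05)
        assert ds.is_empty

    def test_monotone_in_alpha_enrich(self, fast_study):
        coll = fast_study.collections[0]
        sets = [
            build_type3_mrna(fast_study.mrna, fast_study.labels, coll,
                             fast_study.seed_genes, alpha_enrich=a).feature_set
            for a in (0.001, 0.05, 0.5)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestType4Mrna:
    def test_intersection_of_parents(self, fast_study):
        coll = fast_study.collections[0]
        t2 = build_type2(fast_study.mrna, fast_study.labels)
        t3 = build_type3_mrna(fast_study.mrna, fast_study.labels, coll, fast_study.seed_genes)
        t4 = build_type4_mrna(fast_study.mrna, fast_study.labels, coll, fast_study.seed_genes)
        assert t4.feature_set == t2.feature_set & t3.feature_set

    def test_vacuous_de_filter_reduces_to_type3(self, fast_study):
        coll = fast_study.collections[1]
        t3 = build_type3_mrna(fast_study.mrna, fast_study.labels, coll, fast_study.seed_genes)
        t4 = build_type4_mrna(fast_study.mrna, fast_study.labels, coll,
                              fast_study.seed_genes, alpha_de=1.0)
        assert t4.feature_set == t3.feature_set

    def test_provenance_chains_both_filters(self, fast_study):
        coll = fast_study.collections[0]
        t4 = build_type4_mrna(fast_study.mrna, fast_study.labels, coll, fast_study.seed_genes)
        assert len(t4.provenance) >= 3
        assert any("t-test" in p for p in t4.provenance)
        assert any("enrichment" in p for p in t4.provenance)


class TestMirnaTypes:
    def _expr(self, mirnas, n_samples=8, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(tuple(mirnas), tuple(f"S{i}" for i in range(n_samples)),
                                rng.normal(size=(len(mirnas), n_samples)))

    def test_type3_relational_join(self, simple_target_map):
        expr = self._expr(["m1", "m2", "m3", "m4"])
        labels = SampleLabels(expr.sample_ids, np.array([1] * 4 + [0] * 4))
        ds = build_type3_mirna(expr, labels, simple_target_map, seed_genes={"gA"})
        assert ds.feature_set == {"m1", "m3"}

    def test_empty_target_map(self):
        expr = self._expr(["m1", "m2"])
        labels = SampleLabels(expr.sample_ids, np.array([1] * 4 + [0] * 4))
        ds = build_type3_mirna(expr, labels, TargetMap(frozenset()), seed_genes={"gA"})
        assert ds.is_empty

    def test_seed_covering_all_targets(self, simple_target_map):
        expr = self._expr(["m1", "m2", "m3", "m4"])
        labels = SampleLabels(expr.sample_ids, np.array([1] * 4 + [0] * 4))
        ds = build_type3_mirna(expr, labels, simple_target_map,
                               seed_genes={"gA", "gB", "gC"})
        assert ds.feature_set == {"m1", "m2", "m3"}  # m4 has no pair at all

    def test_type4_equals_enumerated_intersection(self, fast_study):
        t2 = build_type2(fast_study.mirna, fast_study.labels)
        t3 = build_type3_mirna(fast_study.mirna, fast_study.labels,
                               fast_study.target_map, fast_study.seed_genes)
        t4 = build_type4_mirna(fast_study.mirna, fast_study.labels,
                               fast_study.target_map, fast_study.seed_genes)
        # independent enumeration of both filters
        oracle_dem = scipy_de_oracle(fast_study.mirna, fast_study.labels, 0.05)
        oracle_targets = {m for m, g in fast_study.target_map.pairs
                          if g in fast_study.seed_genes}
        assert t4.feature_set == oracle_dem & (oracle_targets & set(fast_study.mirna.feature_ids))
        assert t4.feature_set == t2.feature_set & t3.feature_set


class TestBuildAll:
    def test_fourteen_datasets_in_order(self, fast_study):
        config = BuildConfig(
            collections=fast_study.collections,
            seed_genes=fast_study.seed_genes,
            target_map=fast_study.target_map,
        )
        mrna_ds, mirna_ds = build_all(fast_study.mrna, fast_study.mirna,
                                      fast_study.labels, config)
        assert len(mrna_ds) + len(mirna_ds) == 14
        assert [d.tag for d in mrna_ds] == [
            "type1", "type2", "type3-BP", "type3-MF", "type3-CC", "type3-Pathway",
            "type4-BP", "type4-MF", "type4-CC", "type4-Pathway",
        ]
        assert [d.tag for d in mirna_ds] == ["type1", "type2", "type3", "type4"]
        type1_set = mrna_ds[0].feature_set
        for ds in mrna_ds[1:]:
            assert ds.feature_set <= type1_set
        # every type4 variant is exactly type2 ∩ matching type3
        by_tag = {d.tag: d for d in mrna_ds}
        for variant in ("BP", "MF", "CC", "Pathway"):
            assert by_tag[f"type4-{variant}"].feature_set == (
                by_tag["type2"].feature_set & by_tag[f"type3-{variant}"].feature_set
            )

    def test_planted_signal_recovery_type4(self):
        """Genes that are both planted-differential and disease-term members
        survive the combined filter at high rate."""
        cfg = SimulationConfig(rng_seed=17)  # defaults: effect 1.5, bias 0.9
        study = simulate_study(cfg)
        config = BuildConfig(collections=study.collections,
                             seed_genes=study.seed_genes,
                             target_map=study.target_map)
        mrna_ds, _ = build_all(study.mrna, study.mirna, study.labels, config)
        t4_bp = next(d for d in mrna_ds if d.tag == "type4-BP")
        bp = study.collections[0]
        disease_members = frozenset().union(
            *(bp.terms[t] for t in study.truth.disease_terms["BP"])
        )
        both = study.truth.de_genes & disease_members
        assert both  # the stated world plants such genes
        assert len(t4_bp.feature_set & both) / len(both) >= 0.8

    def test_thresholds_validated(self, fast_study):
        with pytest.raises(ValueError):
            BuildConfig(collections=(), seed_genes=frozenset(),
                        target_map=TargetMap(frozenset()), alpha_de=0.0)
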