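import numpy as np
import pytest

from prefilterfs import AnnotationCollection, ExpressionMatrix, SampleLabels, TargetMap
from prefilterfs.synthetic import SimulationConfig, simulate_study


@pytest.fixture
def tiny_matrix():
    return ExpressionMatrix(
        feature_ids=("g1", "g2", "g3"),
        sample_ids=("S1", "S2"),
        values=np.array([[1.0, 2.0], [3.0, 4.5], [0.25, -1.5]]),
    )


@pytest.fixture
def small_labels():
    """10 samples, 6 positive / 4 negative."""
    return SampleLabels(
        tuple(f"S{i}" for i in range(10)),
        np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0]),
    )


@pytest.fixture
def hand_collection():
    """20-gene universe with one disease-like term and two background terms."""
    universe = frozenset(f"g{i}" for i in range(1, 21))
    return AnnotationCollection(
        "BP",
        {
            "D": frozenset({"g1", "g2", "g3", "g4", "g5"}),
            "B1": frozenset({"g6", "g7", "g8"}),
            "B2": frozenset({"g10", "g11", "g12", "g13"}),
        },
        universe,
    )


@pytest.fixture(scope="session")
def fast_sim_config():
    """Reduced-scale study so solver-heavy tests stay fast."""
    return SimulationConfig(
        n_genes=200,
        n_mirnas=30,
        collection_specs=(("BP", 10), ("MF", 10), ("CC", 10), ("Pathway", 10)),
        n_disease_terms=3,
        n_seed_genes=20,
        n_target_pairs=60,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def fast_study(fast_sim_config):
    return simulate_study(fast_sim_config)


@pytest.fixture
def simple_target_map():
    return TargetMap(frozenset({("m1", "gA"), ("m2", "gB"), ("m3", "gA"), ("m3", "gC")}))
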