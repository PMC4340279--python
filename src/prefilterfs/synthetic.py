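"""Synthetic parallel mRNA + microRNA two-class studies.

Emulates the structure of a paired microarray disease study — a
case/control design measured on both an mRNA and a microRNA layer from the
same subjects — with planted differential signal so that every downstream
stage (t-filter, enrichment filter, target-map filter, L1 selection,
cross-validated evaluation) has a known ground truth.

Statistical model
-----------------
Null features are class-independent Gaussians: feature f has baseline
``mu_f ~ Normal(7, 2^2)`` (mimicking log2 microarray intensity) and unit
within-class variance. Planted differential features gain an additive mean
shift of ``effect_size`` standard deviations in the positive class. Seed
(disease) genes are drawn from the planted-differential genes with
probability ``seed_enrichment_bias``; "disease" annotation terms draw at
least ``disease_member_frac`` of their members from seed ∪ planted genes
while background terms draw uniformly; the miRNA target map links planted
miRNAs to seed genes with probability ``target_bias``.

All draws come from one ``numpy.random.default_rng(rng_seed)`` stream in a
fixed documented order: sample labels, planted gene set, mRNA baselines and
matrix, planted miRNA set, miRNA baselines and matrix, seed genes,
collections (in declared order), target map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_model import (
    AnnotationCollection,
    ExpressionMatrix,
    SampleLabels,
    TargetMap,
    write_expression_matrix,
    write_gene_sets,
    write_labels,
    write_seed_genes,
    write_target_map,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and signal of a synthetic study.

    Defaults are the test-scale configuration: 30+30 samples, 500 genes,
    60 miRNAs, four 20-term collections — the full pipeline runs in seconds.
    Use :func:`full_scale_config` for a study with the dimensions of a
    real paired cardiomyopathy microarray cohort.
    """

    n_pos: int = 30
    n_neg: int = 30
    n_genes: int = 500
    n_mirnas: int = 60
    frac_de_genes: float = 0.1
    frac_de_mirnas: float = 0.1
    effect_size: float = 1.5
    collection_specs: tuple[tuple[str, int], ...] = (
        ("BP", 20),
        ("MF", 20),
        ("CC", 20),
        ("Pathway", 20),
    )
    term_size_range: tuple[int, int] = (5, 25)
    n_disease_terms: int = 5
    disease_member_frac: float = 0.8
    n_seed_genes: int = 40
    seed_enrichment_bias: float = 0.9
    n_target_pairs: int = 150
    target_bias: float = 0.8
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_pos", "n_neg", "n_genes", "n_mirnas", "n_seed_genes", "n_target_pairs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_de_genes",
            "frac_de_mirnas",
            "seed_enrichment_bias",
            "target_bias",
            "disease_member_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size > 0:
            if self.frac_de_genes * self.n_genes < 1:
                raise ValueError("frac_de_genes * n_genes must be >= 1")
            if self.frac_de_mirnas * self.n_mirnas < 1:
                raise ValueError("frac_de_mirnas * n_mirnas must be >= 1")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError("term_size_range must satisfy 1 <= lo <= hi <= n_genes")


def full_scale_config(rng_seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with the dimensions of the motivating study:
    106 cases + 20 controls, 18756 genes, 819 mature miRNAs, 372 seed
    genes, GO BP/MF/CC collections of 5140/2782/851 terms, 2999 pathways,
    and 19550 validated miRNA-target pairs."""
    defaults = dict(
        n_pos=106,
        n_neg=20,
        n_genes=18756,
        n_mirnas=819,
        collection_specs=(("BP", 5140), ("MF", 2782), ("CC", 851), ("Pathway", 2999)),
        n_disease_terms=50,
        n_seed_genes=372,
        n_target_pairs=19550,
        rng_seed=rng_seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@dataclass(frozen=True)
class StudyTruth:
    """Planted ground truth: the differential features and disease terms."""

    de_genes: frozenset[str]
    de_mirnas: frozenset[str]
    disease_terms: dict[str, tuple[str, ...]]  # collection name -> term IDs


@dataclass(frozen=True)
class SyntheticStudy:
    mrna: ExpressionMatrix
    mirna: ExpressionMatrix
    labels: SampleLabels
    collections: tuple[AnnotationCollection, ...]
    seed_genes: frozenset[str]
    target_map: TargetMap
    truth: StudyTruth
    config: SimulationConfig


def _expression_layer(
    rng: np.random.Generator,
    feature_ids: tuple[str, ...],
    n_de: int,
    y: np.ndarray,
    effect_size: float,
) -> tuple[np.ndarray, frozenset[str]]:
    n_features, n_samples = len(feature_ids), len(y)
    de_idx = np.sort(rng.choice(n_features, size=n_de, replace=False)) if n_de else np.array([], int)
    baseline = rng.normal(7.0, 2.0, size=n_features)
    values = rng.normal(0.0, 1.0, size=(n_features, n_samples)) + baseline[:, None]
    if n_de:
        values[np.ix_(de_idx, np.where(y == 1)[0])] += effect_size
    return values, frozenset(feature_ids[i] for i in de_idx)


def _biased_sample(
    rng: np.random.Generator,
    preferred: list[str],
    other: list[str],
    k: int,
    bias: float,
) -> list[str]:
    """Draw k items without replacement; each slot prefers ``preferred``
    with probability ``bias``, falling back when a pool is exhausted."""
    n_pref = int(rng.binomial(k, bias))
    n_pref = min(n_pref, len(preferred))
    n_other = min(k - n_pref, len(other))
    n_pref = min(k - n_other, len(preferred))  # refill if `other` was short
    picked = list(rng.choice(preferred, size=n_pref, replace=False)) if n_pref else []
    picked += list(rng.choice(other, size=n_other, replace=False)) if n_other else []
    return picked


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a fully reproducible paired two-class study.

    Two calls with the same configuration (including ``rng_seed``) produce
    bit-identical studies.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_pos + config.n_neg
    sample_ids = tuple(f"S{i + 1:04d}" for i in range(n))
    y = np.array([1] * config.n_pos + [0] * config.n_neg)
    labels = SampleLabels(sample_ids, y)

    gene_ids = tuple(f"G{i + 1:05d}" for i in range(config.n_genes))
    mirna_ids = tuple(f"miR-{i + 1:04d}" for i in range(config.n_mirnas))

    n_de_genes = int(round(config.frac_de_genes * config.n_genes)) if config.effect_size > 0 else 0
    n_de_mirnas = int(round(config.frac_de_mirnas * config.n_mirnas)) if config.effect_size > 0 else 0
    gene_values, de_genes = _expression_layer(rng, gene_ids, n_de_genes, y, config.effect_size)
    mirna_values, de_mirnas = _expression_layer(rng, mirna_ids, n_de_mirnas, y, config.effect_size)
    mrna = ExpressionMatrix(gene_ids, sample_ids, gene_values)
    mirna = ExpressionMatrix(mirna_ids, sample_ids, mirna_values)

    planted = sorted(de_genes)
    background = sorted(set(gene_ids) - de_genes)
    seed_genes = frozenset(
        _biased_sample(rng, planted, background, config.n_seed_genes, config.seed_enrichment_bias)
    )

    disease_pool = sorted(seed_genes | de_genes)
    all_genes = sorted(gene_ids)
    lo, hi = config.term_size_range
    collections = []
    truth_terms: dict[str, tuple[str, ...]] = {}
    for name, n_terms in config.collection_specs:
        terms: dict[str, frozenset[str]] = {}
        n_dis = min(config.n_disease_terms, n_terms)
        for t in range(n_terms):
            size = int(rng.integers(lo, hi + 1))
            term_id = f"{name}:{t + 1:04d}"
            if t < n_dis:
                n_from_pool = min(int(np.ceil(config.disease_member_frac * size)), len(disease_pool))
                members = list(rng.choice(disease_pool, size=n_from_pool, replace=False))
                filler_pool = sorted(set(all_genes) - set(members))
                n_fill = size - n_from_pool
                if n_fill:
                    members += list(rng.choice(filler_pool, size=n_fill, replace=False))
            else:
                members = list(rng.choice(all_genes, size=size, replace=False))
            terms[term_id] = frozenset(members)
        collections.append(AnnotationCollection(name, terms, frozenset(gene_ids)))
        truth_terms[name] = tuple(sorted(terms)[:n_dis])

    planted_mirnas = sorted(de_mirnas) or sorted(mirna_ids)
    seed_list = sorted(seed_genes)
    pairs: set[tuple[str, str]] = set()
    attempts = 0
    max_attempts = 50 * config.n_target_pairs
    while len(pairs) < config.n_target_pairs and attempts < max_attempts:
        attempts += 1
        if rng.random() < config.target_bias:
            m = planted_mirnas[int(rng.integers(len(planted_mirnas)))]
            g = seed_list[int(rng.integers(len(seed_list)))]
        else:
            m = mirna_ids[int(rng.integers(config.n_mirnas))]
            g = all_genes[int(rng.integers(config.n_genes))]
        pairs.add((m, g))
    if len(pairs) < config.n_target_pairs:
        logger.warning(
            "target map saturated at %d unique pairs (%d requested)",
            len(pairs),
            config.n_target_pairs,
        )
    target_map = TargetMap(frozenset(pairs))

    truth = StudyTruth(de_genes, de_mirnas, truth_terms)
    return SyntheticStudy(
        mrna, mirna, labels, tuple(collections), seed_genes, target_map, truth, config
    )


def write_study(study: SyntheticStudy, directory) -> list[dict]:
    """Write every study artifact in its on-disk dialect plus a truth file.

    Returns a manifest: one record per file with its path and record count.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def note(path: Path, records: int):
        manifest.append({"path": str(path), "records": records})

    p = directory / "mrna.tsv"
    write_expression_matrix(study.mrna, p)
    note(p, study.mrna.n_features)
    p = directory / "mirna.tsv"
    write_expression_matrix(study.mirna, p)
    note(p, study.mirna.n_features)
    p = directory / "labels.tsv"
    write_labels(study.labels, p)
    note(p, study.labels.n_samples)
    for coll in study.collections:
        p = directory / f"{coll.collection_name}.gmt"
        write_gene_sets(coll, p)
        note(p, coll.n_terms)
    p = directory / "seed_genes.txt"
    write_seed_genes(study.seed_genes, p)
    note(p, len(study.seed_genes))
    p = directory / "targets.tsv"
    write_target_map(study.target_map, p)
    note(p, len(study.target_map.pairs))
    p = directory / "truth.json"
    truth = {
        "de_genes": sorted(study.truth.de_genes),
        "de_mirnas": sorted(study.truth.de_mirnas),
        "disease_terms": {k: list(v) for k, v in study.truth.disease_terms.items()},
    }
    with open(p, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    note(p, len(truth["de_genes"]) + len(truth["de_mirnas"]))
    return manifest
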