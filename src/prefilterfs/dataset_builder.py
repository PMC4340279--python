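"""Construction of the pre-filtered dataset types.

For an mRNA layer, ten datasets are built:

* type1 — all features (identity filter);
* type2 — differentially expressed features (two-sample t-test, p <= alpha);
* type3-{BP,MF,CC,Pathway} — features annotated to at least one term that is
  enriched (hypergeometric, p <= alpha) in the disease seed-gene list, one
  dataset per annotation collection;
* type4-{BP,MF,CC,Pathway} — the intersection of type2 and the matching
  type3: differentially expressed features with disease-related annotation.

For a microRNA layer, four datasets: type1 and type2 as above, type3 keeps
miRNAs with at least one validated target in the seed genes, and type4 is
the type2/type3 intersection.

Empty outcomes are valid datasets, logged with a warning; downstream stages
must refuse them explicitly rather than have them silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io_model import (
    AnnotationCollection,
    ExpressionMatrix,
    FilteredDataset,
    SampleLabels,
    TargetMap,
    restrict_to_universe,
)
from .stat_tests import enrich, t_test_matrix

logger = logging.getLogger(__name__)

#: canonical dataset ordering, mirroring the comparative-table layout
MRNA_ORDER = (
    "type1",
    "type2",
    "type3-BP",
    "type3-MF",
    "type3-CC",
    "type3-Pathway",
    "type4-BP",
    "type4-MF",
    "type4-CC",
    "type4-Pathway",
)
MIRNA_ORDER = ("type1", "type2", "type3", "type4")


@dataclass(frozen=True)
class BuildConfig:
    """Thresholds and biological knowledge for the pre-filters."""

    collections: tuple[AnnotationCollection, ...]
    seed_genes: frozenset[str]
    target_map: TargetMap
    alpha_de: float = 0.05
    alpha_enrich: float = 0.05
    equal_var: bool = False  # Student t instead of Welch when True

    def __post_init__(self):
        if not (0 < self.alpha_de <= 1 and 0 < self.alpha_enrich <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        object.__setattr__(self, "collections", tuple(self.collections))
        object.__setattr__(self, "seed_genes", frozenset(self.seed_genes))


def _warn_if_empty(ds: FilteredDataset) -> FilteredDataset:
    if ds.is_empty:
        logger.warning("dataset %s is empty after filtering", ds.tag)
    return ds


def build_type1(expr: ExpressionMatrix, labels: SampleLabels) -> FilteredDataset:
    """Identity filter: all features on the array, order preserved."""
    return FilteredDataset(
        "type1",
        expr,
        labels,
        provenance=(f"identity: {expr.n_features} features",),
    )


def de_feature_set(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    alpha_de: float = 0.05,
    equal_var: bool = False,
) -> frozenset[str]:
    """Features differentially expressed at p <= alpha_de (inclusive)."""
    y = labels.aligned_to(expr.sample_ids)
    _, p = t_test_matrix(expr.values, y, equal_var=equal_var)
    return frozenset(f for f, pv in zip(expr.feature_ids, p) if pv <= alpha_de)


def build_type2(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    alpha_de: float = 0.05,
    equal_var: bool = False,
) -> FilteredDataset:
    """Statistical pre-filter: keep features with t-test p <= alpha_de."""
    kept = de_feature_set(expr, labels, alpha_de, equal_var)
    matrix = expr.subset_features(kept)
    test = "Student t" if equal_var else "Welch t"
    prov = (
        f"{test}-test p<={alpha_de}: {expr.n_features} -> {matrix.n_features} features",
    )
    return _warn_if_empty(FilteredDataset("type2", matrix, labels, provenance=prov))


def disease_annotated_features(
    coll: AnnotationCollection,
    seed_genes,
    alpha_enrich: float = 0.05,
) -> tuple[frozenset[str], int]:
    """Features annotated to >=1 term enriched in the seed-gene list.

    Returns (feature set, number of enriched terms). The collection must
    already be restricted to the array's feature universe.
    """
    enriched = enrich(seed_genes, coll, alpha=alpha_enrich)
    kept: set[str] = set()
    for term in enriched:
        kept |= coll.terms[term.term_id]
    return frozenset(kept), len(enriched)


def build_type3_mrna(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    coll: AnnotationCollection,
    seed_genes,
    alpha_enrich: float = 0.05,
) -> FilteredDataset:
    """Biological pre-filter: keep features sharing an enriched term with
    the disease seed genes. One dataset per annotation collection."""
    coll = restrict_to_universe(coll, expr.feature_ids)
    kept, n_enriched = disease_annotated_features(coll, seed_genes, alpha_enrich)
    matrix = expr.subset_features(kept)
    prov = (
        f"enrichment({coll.collection_name}) p<={alpha_enrich}: "
        f"{n_enriched} enriched terms; {expr.n_features} -> {matrix.n_features} features",
    )
    return _warn_if_empty(
        FilteredDataset("type3", matrix, labels, variant=coll.collection_name, provenance=prov)
    )


def build_type4_mrna(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    coll: AnnotationCollection,
    seed_genes,
    alpha_de: float = 0.05,
    alpha_enrich: float = 0.05,
    equal_var: bool = False,
) -> FilteredDataset:
    """Combined pre-filter: exact intersection of type2 and type3 features."""
    t2 = build_type2(expr, labels, alpha_de, equal_var)
    t3 = build_type3_mrna(expr, labels, coll, seed_genes, alpha_enrich)
    kept = t2.feature_set & t3.feature_set
    matrix = expr.subset_features(kept)
    prov = t2.provenance + t3.provenance + (
        f"intersection: {matrix.n_features} features",
    )
    return _warn_if_empty(
        FilteredDataset("type4", matrix, labels, variant=t3.variant, provenance=prov)
    )


def build_type3_mirna(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    target_map: TargetMap,
    seed_genes,
) -> FilteredDataset:
    """Keep miRNAs with >=1 validated target among the disease seed genes."""
    kept = target_map.mirnas_targeting(seed_genes) & set(expr.feature_ids)
    matrix = expr.subset_features(kept)
    prov = (
        f"target-map filter: {expr.n_features} -> {matrix.n_features} miRNAs "
        f"targeting {len(frozenset(seed_genes))} seed genes",
    )
    return _warn_if_empty(FilteredDataset("type3", matrix, labels, provenance=prov))


def build_type4_mirna(
    expr: ExpressionMatrix,
    labels: SampleLabels,
    target_map: TargetMap,
    seed_genes,
    alpha_de: float = 0.05,
    equal_var: bool = False,
) -> FilteredDataset:
    """Differentially expressed miRNAs that also target a seed gene."""
    t2 = build_type2(expr, labels, alpha_de, equal_var)
    t3 = build_type3_mirna(expr, labels, target_map, seed_genes)
    kept = t2.feature_set & t3.feature_set
    matrix = expr.subset_features(kept)
    prov = t2.provenance + t3.provenance + (
        f"intersection: {matrix.n_features} miRNAs",
    )
    return _warn_if_empty(FilteredDataset("type4", matrix, labels, provenance=prov))


def build_all_mrna(
    expr: ExpressionMatrix, labels: SampleLabels, config: BuildConfig
) -> list[FilteredDataset]:
    """The ten mRNA datasets in canonical order (type1, type2, 4x type3, 4x type4)."""
    datasets = [
        build_type1(expr, labels),
        build_type2(expr, labels, config.alpha_de, config.equal_var),
    ]
    for coll in config.collections:
        datasets.append(
            build_type3_mrna(expr, labels, coll, config.seed_genes, config.alpha_enrich)
        )
    for coll in config.collections:
        datasets.append(
            build_type4_mrna(
                expr,
                labels,
                coll,
                config.seed_genes,
                config.alpha_de,
                config.alpha_enrich,
                config.equal_var,
            )
        )
    return datasets


def build_all_mirna(
    expr: ExpressionMatrix, labels: SampleLabels, config: BuildConfig
) -> list[FilteredDataset]:
    """The four microRNA datasets in canonical order."""
    return [
        build_type1(expr, labels),
        build_type2(expr, labels, config.alpha_de, config.equal_var),
        build_type3_mirna(expr, labels, config.target_map, config.seed_genes),
        build_type4_mirna(
            expr, labels, config.target_map, config.seed_genes, config.alpha_de, config.equal_var
        ),
    ]


def build_all(
    mrna: ExpressionMatrix,
    mirna: ExpressionMatrix,
    labels: SampleLabels,
    config: BuildConfig,
) -> tuple[list[FilteredDataset], list[FilteredDataset]]:
    """Build every dataset of both layers; with four annotation collections
    this yields 10 mRNA + 4 miRNA = 14 datasets in deterministic order."""
    mrna_ds = build_all_mrna(mrna, labels, config)
    mirna_ds = build_all_mirna(mirna, labels, config)
    logger.info(
        "built %d mRNA and %d miRNA datasets", len(mrna_ds), len(mirna_ds)
    )
    return mrna_ds, mirna_ds
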