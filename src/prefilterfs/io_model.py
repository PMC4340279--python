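"""Core data model and readers/writers for every on-disk artifact.

On-disk dialects
----------------
* Expression matrices: TSV; header row = sample IDs, first column = feature
  IDs, numeric body. Rows are features, columns are samples.
* Gene sets: GMT (tab-separated: term ID, description, member IDs...).
* Target map and probe map: headerless two-column TSV.
* Labels: two-column TSV (sample ID, label); seed genes: one ID per line.

Numeric values are written with 6 significant digits (``%.6g``); a
write/read round trip is bit-exact for values already representable at
that precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousMappingError,
    FormatError,
    IdentifierCollisionError,
)

logger = logging.getLogger(__name__)

#: numeric format used by all matrix writers; documented so round-trip
#: tests can be exact.
FLOAT_FORMAT = "%.6g"


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise IdentifierCollisionError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A features x samples real-valued matrix (log-scale expression).

    Rows are indexed by ``feature_ids``, columns by ``sample_ids``; both
    orders are preserved from the source. All entries must be finite.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must all be finite")
        object.__setattr__(self, "values", values)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.feature_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            feature_ids=tuple(str(i) for i in frame.index),
            sample_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        """Restrict to the given features, preserving this matrix's row order."""
        wanted = set(feature_ids)
        keep = [i for i, f in enumerate(self.feature_ids) if f in wanted]
        return ExpressionMatrix(
            feature_ids=tuple(self.feature_ids[i] for i in keep),
            sample_ids=self.sample_ids,
            values=self.values[keep, :],
        )


@dataclass(frozen=True)
class SampleLabels:
    """Binary class labels aligned to sample IDs; 1 = disease (positive)."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray  # int array of 0/1

    def __post_init__(self):
        _check_unique(self.sample_ids, "sample")
        labels = np.asarray(self.labels, dtype=int)
        if labels.shape != (len(self.sample_ids),):
            raise ValueError("labels must align one-to-one with sample_ids")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be coded 0/1")
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def aligned_to(self, sample_ids) -> np.ndarray:
        """Label vector reordered to the given sample IDs."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValueError(f"labels missing for samples: {missing[:5]}")
        return self.labels[[pos[s] for s in sample_ids]]


@dataclass(frozen=True)
class AnnotationCollection:
    """Named gene sets (term ID -> member feature IDs) over a declared universe.

    The universe is the background of the hypergeometric enrichment test:
    ``b`` is its size, and each term's ``a`` is the term's size after
    restriction to it.
    """

    collection_name: str
    terms: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self):
        object.__setattr__(
            self,
            "terms",
            {t: frozenset(m) for t, m in self.terms.items()},
        )
        object.__setattr__(self, "universe", frozenset(self.universe))

    @property
    def n_terms(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class TargetMap:
    """Validated many-to-many miRNA -> gene regulatory pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self):
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError("target-map identifiers must be non-empty")
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def mirnas_targeting(self, genes) -> frozenset[str]:
        genes = set(genes)
        return frozenset(m for m, g in self.pairs if g in genes)


@dataclass(frozen=True)
class FilteredDataset:
    """An expression matrix restricted to a pre-filter's surviving features.

    ``dataset_type`` is one of type1..type4; ``variant`` tags the annotation
    collection for mRNA types 3-4 (BP/MF/CC/Pathway). ``provenance`` records
    each filter applied (test, threshold, before/after counts) and must be
    non-empty for types 2-4.
    """

    dataset_type: str
    matrix: ExpressionMatrix
    labels: SampleLabels
    variant: str | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.dataset_type not in {"type1", "type2", "type3", "type4"}:
            raise ValueError(f"unknown dataset type {self.dataset_type!r}")
        if self.dataset_type != "type1" and not self.provenance:
            raise ValueError("types 2-4 require non-empty provenance")

    @property
    def tag(self) -> str:
        return self.dataset_type if self.variant is None else f"{self.dataset_type}-{self.variant}"

    @property
    def feature_set(self) -> frozenset[str]:
        return frozenset(self.matrix.feature_ids)

    @property
    def is_empty(self) -> bool:
        return self.matrix.n_features == 0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample IDs, col 1 = feature IDs).

    Raises :class:`IdentifierCollisionError` on duplicate IDs and
    :class:`FormatError` (with the offending line number) on non-numeric
    cells or ragged rows.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError("empty expression file", line=1)
        sample_ids = header.split("\t")[1:]
        _check_unique(sample_ids, "sample")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise FormatError(
                    f"expected {len(sample_ids) + 1} fields, found {len(parts)}",
                    line=lineno,
                )
            feature_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"non-numeric cell: {exc}", line=lineno) from None
    _check_unique(feature_ids, "feature")
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(sample_ids)))
    if rows and not np.all(np.isfinite(values)):
        bad = int(np.where(~np.all(np.isfinite(values), axis=1))[0][0])
        raise FormatError("non-finite expression value", line=bad + 2)
    return ExpressionMatrix(tuple(feature_ids), tuple(sample_ids), values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label="feature")


def read_labels(path) -> SampleLabels:
    """Read a headerless two-column TSV of (sample ID, label).

    Labels may be arbitrary strings; exactly two distinct values must be
    present and they are coded 0/1 by sorted order unless already 0/1.
    """
    sample_ids: list[str] = []
    raw: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError("label lines must have exactly 2 fields", line=lineno)
            sample_ids.append(parts[0])
            raw.append(parts[1])
    distinct = sorted(set(raw))
    if len(distinct) != 2:
        raise FormatError(f"expected exactly 2 label values, found {distinct}")
    if distinct == ["0", "1"]:
        coding = {"0": 0, "1": 1}
    else:
        coding = {distinct[0]: 0, distinct[1]: 1}
        logger.info("label coding: %r -> 0, %r -> 1", distinct[0], distinct[1])
    return SampleLabels(tuple(sample_ids), np.array([coding[r] for r in raw]))


def write_labels(labels: SampleLabels, path) -> None:
    with open(path, "w") as fh:
        for s, y in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}\t{int(y)}\n")


def read_gene_sets(path, collection_name: str | None = None) -> AnnotationCollection:
    """Read a GMT file. The universe defaults to the union of all members
    until :func:`restrict_to_universe` fixes an explicit background."""
    terms: dict[str, frozenset[str]] = {}
    universe: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("GMT lines need >= 3 tab-separated fields", line=lineno)
            term, _desc, *members = parts
            members = [m for m in members if m]
            if term in terms:
                raise FormatError(f"duplicate term {term!r}", line=lineno)
            terms[term] = frozenset(members)
            universe.update(members)
    if not terms:
        logger.warning("GMT file %s is empty", path)
    name = collection_name if collection_name is not None else str(path)
    return AnnotationCollection(name, terms, frozenset(universe))


def write_gene_sets(coll: AnnotationCollection, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(coll.terms):
            members = "\t".join(sorted(coll.terms[term]))
            fh.write(f"{term}\t{coll.collection_name}\t{members}\n")


def restrict_to_universe(coll: AnnotationCollection, universe) -> AnnotationCollection:
    """Intersect every term with ``universe`` and fix it as the background.

    Terms emptied by the intersection are dropped. Idempotent.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    terms = {}
    for term, members in coll.terms.items():
        kept = members & universe
        if kept:
            terms[term] = kept
    dropped = coll.n_terms - len(terms)
    if dropped:
        logger.info(
            "restrict_to_universe(%s): dropped %d terms emptied by restriction",
            coll.collection_name,
            dropped,
        )
    return replace(coll, terms=terms, universe=universe)


def _read_two_column(path, what: str) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{what} lines must have exactly 2 fields", line=lineno)
            out.append((parts[0], parts[1]))
    return out


def read_target_map(path) -> TargetMap:
    """Headerless two-column TSV of (miRNA ID, gene ID); duplicates collapse."""
    return TargetMap(frozenset(_read_two_column(path, "target-map")))


def write_target_map(tmap: TargetMap, path) -> None:
    with open(path, "w") as fh:
        for m, g in sorted(tmap.pairs):
            fh.write(f"{m}\t{g}\n")


def read_seed_genes(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def write_seed_genes(genes, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")


def read_probe_map(path) -> dict[str, str]:
    """Headerless two-column TSV of (probe ID, feature ID).

    A probe listed with two different features is an ambiguity the caller
    must resolve upstream; we refuse rather than guess.
    """
    mapping: dict[str, str] = {}
    for probe, feat in _read_two_column(path, "probe-map"):
        if probe in mapping and mapping[probe] != feat:
            raise AmbiguousMappingError(
                f"probe {probe!r} maps to both {mapping[probe]!r} and {feat!r}"
            )
        mapping[probe] = feat
    return mapping


def collapse_probes(
    matrix: ExpressionMatrix,
    mapping: dict[str, str],
    rule: str = "mean",
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per mapped feature.

    Multiple probes for a feature are summarized per sample by ``rule``
    (``mean`` default, ``median`` available); unmapped probes are dropped
    and the before/after counts logged.
    """
    unknown = [p for p in mapping if p not in set(matrix.feature_ids)]
    if unknown:
        raise ValueError(f"mapping keys absent from matrix: {unknown[:5]}")
    if rule not in {"mean", "median"}:
        raise ValueError(f"unknown collapse rule {rule!r}")
    groups: dict[str, list[int]] = {}
    order: list[str] = []
    for i, probe in enumerate(matrix.feature_ids):
        feat = mapping.get(probe)
        if feat is None:
            continue
        if feat not in groups:
            groups[feat] = []
            order.append(feat)
        groups[feat].append(i)
    reducer = np.mean if rule == "mean" else np.median
    values = np.array(
        [reducer(matrix.values[idx, :], axis=0) for idx in (groups[f] for f in order)]
    ) if order else np.empty((0, matrix.n_samples))
    logger.info(
        "collapse_probes: %d probes -> %d features (rule=%s)",
        matrix.n_features,
        len(order),
        rule,
    )
    return ExpressionMatrix(tuple(order), matrix.sample_ids, values)
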