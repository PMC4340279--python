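"""End-to-end orchestration: simulate/read -> build -> select -> evaluate.

The report mirrors the comparative layout of the study tables: one row per
built dataset with its raw variable count, surviving features, selected
features, percent reduction, pooled cross-validated AUC/precision and wall
time; an overlap section per layer; and an enriched-term-coverage section
for the mRNA selections.

Reproducibility: a single top-level seed deterministically derives every
stage seed through ``numpy.random.SeedSequence(seed).spawn`` in a fixed
order — simulation, fold assignment, solver — so two runs with the same
configuration and seed produce identical reports up to timings.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .dataset_builder import BuildConfig, build_all
from .evaluation import (
    CVResult,
    OverlapReport,
    cross_validate,
    overlap_analysis,
    percent_reduction,
    term_coverage,
)
from .io_model import (
    AnnotationCollection,
    ExpressionMatrix,
    FilteredDataset,
    SampleLabels,
    TargetMap,
    read_expression_matrix,
    read_gene_sets,
    read_labels,
    read_seed_genes,
    read_target_map,
    restrict_to_universe,
)
from .l1_logistic import SelectionResult, SolverConfig, select_features
from .synthetic import SimulationConfig, SyntheticStudy, simulate_study

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InputPaths:
    """On-disk inputs for a run on real (non-simulated) data."""

    mrna: str
    mirna: str
    labels: str
    gene_sets: tuple[tuple[str, str], ...]  # (collection name, GMT path)
    seed_genes: str
    targets: str


@dataclass(frozen=True)
class PipelineConfig:
    """Exactly one of ``simulation`` / ``paths`` drives the run."""

    simulation: SimulationConfig | None = None
    paths: InputPaths | None = None
    alpha_de: float = 0.05
    alpha_enrich: float = 0.05
    solver: SolverConfig = field(default_factory=SolverConfig)
    strategy: str = "inner-cv"
    k: int = 5
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.paths is None):
            raise ValueError("provide exactly one of simulation config or input paths")


@dataclass
class ReportRow:
    layer: str  # "mRNA" or "miRNA"
    tag: str  # e.g. "type3-BP"
    raw_variables: int
    kept_features: int
    selected_features: int
    percent_reduction: float
    auc: float
    precision: float
    elapsed_seconds: float
    skipped: bool = False


@dataclass
class EvaluationReport:
    rows: list[ReportRow]
    selections: dict[str, list[str]]  # "<layer>/<tag>" -> selected feature IDs
    overlap: dict[str, dict]  # layer -> overlap summary
    coverage: dict[str, dict[str, float]]  # mRNA tag -> collection -> fraction
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "rows": [asdict(r) for r in self.rows],
            "selections": self.selections,
            "overlap": self.overlap,
            "coverage": self.coverage,
            "metadata": self.metadata,
        }


def _overlap_summary(report: OverlapReport) -> dict:
    return {
        "tags": list(report.tags),
        "pairwise_counts": report.pairwise_counts.tolist(),
        "occurrences": dict(sorted(report.occurrences.items())),
        "recurrent_features": list(report.recurrent_features),
    }


def load_inputs(paths: InputPaths):
    mrna = read_expression_matrix(paths.mrna)
    mirna = read_expression_matrix(paths.mirna)
    labels = read_labels(paths.labels)
    collections = tuple(
        read_gene_sets(path, collection_name=name) for name, path in paths.gene_sets
    )
    seed_genes = read_seed_genes(paths.seed_genes)
    targets = read_target_map(paths.targets)
    return mrna, mirna, labels, collections, seed_genes, targets


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Run the full comparative pipeline and assemble the report.

    Empty datasets produce a row flagged ``skipped`` with NaN metrics; the
    run completes. Any other stage failure aborts with the dataset tag.
    """
    ss = np.random.SeedSequence(config.seed)
    sim_seed, fold_seed, solver_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))

    if config.simulation is not None:
        sim = replace(config.simulation, rng_seed=sim_seed)
        study = simulate_study(sim)
        mrna, mirna, labels = study.mrna, study.mirna, study.labels
        collections, seed_genes, targets = study.collections, study.seed_genes, study.target_map
    else:
        mrna, mirna, labels, collections, seed_genes, targets = load_inputs(config.paths)

    collections = tuple(restrict_to_universe(c, mrna.feature_ids) for c in collections)
    build = BuildConfig(
        collections=collections,
        seed_genes=seed_genes,
        target_map=targets,
        alpha_de=config.alpha_de,
        alpha_enrich=config.alpha_enrich,
    )
    mrna_ds, mirna_ds = build_all(mrna, mirna, labels, build)

    solver = replace(config.solver, seed=solver_seed)
    rows: list[ReportRow] = []
    selections: dict[str, list[str]] = {}
    layer_selections: dict[str, list[SelectionResult]] = {"mRNA": [], "miRNA": []}

    for layer, datasets, raw in (("mRNA", mrna_ds, mrna), ("miRNA", mirna_ds, mirna)):
        for ds in datasets:
            reduction = percent_reduction(raw.n_features, ds.matrix.n_features)
            if ds.is_empty:
                logger.warning("skipping metrics for empty dataset %s/%s", layer, ds.tag)
                rows.append(
                    ReportRow(layer, ds.tag, raw.n_features, 0, 0, reduction,
                              math.nan, math.nan, 0.0, skipped=True)
                )
                continue
            sel = select_features(ds, solver, strategy=config.strategy)
            cv = cross_validate(ds, solver, k=config.k, seed=fold_seed, strategy=config.strategy)
            logger.info(
                "%s/%s: %d -> %d features, %d selected, AUC %.3f, precision %.3f",
                layer, ds.tag, raw.n_features, ds.matrix.n_features,
                len(sel.selected_features), cv.auc, cv.precision,
            )
            rows.append(
                ReportRow(
                    layer, ds.tag, raw.n_features, ds.matrix.n_features,
                    len(sel.selected_features), reduction, cv.auc, cv.precision,
                    cv.elapsed_seconds,
                )
            )
            selections[f"{layer}/{ds.tag}"] = list(sel.selected_features)
            layer_selections[layer].append(sel)

    overlap = {
        layer: _overlap_summary(overlap_analysis(sels))
        for layer, sels in layer_selections.items()
        if len(sels) >= 2
    }

    coverage: dict[str, dict[str, float]] = {}
    for sel in layer_selections["mRNA"]:
        coverage[sel.tag] = {
            coll.collection_name: term_coverage(
                sel.feature_set, seed_genes, coll, alpha=config.alpha_enrich
            )
            for coll in collections
        }

    metadata = {
        "seed": config.seed,
        "stage_seeds": {"simulation": sim_seed, "folds": fold_seed, "solver": solver_seed},
        "k": config.k,
        "alpha_de": config.alpha_de,
        "alpha_enrich": config.alpha_enrich,
        "strategy": config.strategy,
        "n_datasets": len(rows),
    }
    return EvaluationReport(rows, selections, overlap, coverage, metadata)


def render_report(report: EvaluationReport, out_dir, formats=("json", "tsv", "markdown")) -> list[str]:
    """Serialize the report deterministically; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt == "json":
            path = out_dir / "report.json"
            with open(path, "w") as fh:
                json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
        elif fmt == "tsv":
            path = out_dir / "report.tsv"
            cols = ["layer", "tag", "raw_variables", "kept_features", "selected_features",
                    "percent_reduction", "auc", "precision", "elapsed_seconds", "skipped"]
            with open(path, "w") as fh:
                fh.write("\t".join(cols) + "\n")
                for r in report.rows:
                    d = asdict(r)
                    fh.write("\t".join(str(d[c]) for c in cols) + "\n")
        elif fmt == "markdown":
            path = out_dir / "report.md"
            with open(path, "w") as fh:
                for layer in ("mRNA", "miRNA"):
                    fh.write(f"## {layer} datasets\n\n")
                    fh.write("| Dataset | Raw variables | Kept | Selected | Reduction (%) | AUC | Precision |\n")
                    fh.write("|---|---|---|---|---|---|---|\n")
                    for r in report.rows:
                        if r.layer != layer:
                            continue
                        fh.write(
                            f"| {r.tag} | {r.raw_variables} | {r.kept_features} | "
                            f"{r.selected_features} | {r.percent_reduction:.2f} | "
                            f"{r.auc:.4f} | {r.precision:.4f} |\n"
                        )
                    fh.write("\n")
        else:
            raise ValueError(f"unknown report format {fmt!r}")
        written.append(str(path))
    return written
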