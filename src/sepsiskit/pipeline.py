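"""End-to-end orchestration: config, stages, report bundle.

``run_pipeline`` reads the three standard inputs (expression TSV, sample
sheet, probe annotation), runs the selection, concordance, DFR,
class-prediction and enrichment stages, and writes a bundle of TSV/JSON
reports into an output directory together with a manifest carrying the
config hash and seed, so a rerun with the same inputs is bit-identical
and self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .concordance import UNION, model_concordance
from .dfr import SQUARED, build_reference, dfr_scores, group_dfr
from .errors import DesignError, ValidationError
from .filtering import (
    THREE_CLASS,
    cluster_order,
    collapse_and_overlap,
    cv_filter,
    f_test_selection,
    per_model_selection,
)
from .genesets import enrichment_table, gene_level_change
from .io import (
    DEFAULT_CLASS_MAP,
    align_annotations,
    read_expression,
    read_gene_sets,
    read_probe_annotation,
    read_sample_annotation,
)
from .prediction import permutation_pvalue
from .simulate import MODEL_A, MODEL_B

log = logging.getLogger("sepsiskit.pipeline")


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from YAML."""

    expression_path: str
    samples_path: str
    probes_path: str
    gene_sets_path: str | None = None
    output_dir: str = "sepsiskit_out"
    class_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))
    cv_threshold: float = 0.5
    cv_scale: str = "linear"
    f_alpha: float = 0.001
    f_grouping: str = THREE_CLASS
    fold_threshold: float = 2.0
    universe_rule: str = UNION
    dfr_variant: str = SQUARED
    reselect_per_fold: bool = True
    n_permutations: int = 1000
    seed: int = 0
    write_cluster_order: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.f_alpha < 1:
            raise DesignError(f"f_alpha must lie in (0, 1), got {self.f_alpha}")
        if self.cv_threshold < 0:
            raise DesignError("cv_threshold must be non-negative")
        if self.fold_threshold < 1:
            raise DesignError("fold_threshold must be >= 1")
        if self.n_permutations < 1:
            raise DesignError("n_permutations must be >= 1")
        if self.seed is None:
            raise DesignError("seed is mandatory (stochastic stages)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_selection(sel, probes, path: Path, name: str) -> dict:
    table = sel.statistic.to_frame()
    if sel.extra is not None:
        table = table.join(sel.extra)
    table["kept"] = table.index.isin(sel.kept)
    table = table.join(probes)
    table.to_csv(path, sep="\t")
    genes = sel.gene_symbols(probes)
    log.info("%s: %d probes kept (%d genes)", name, sel.n_probes_kept, len(genes))
    return {"probes_kept": sel.n_probes_kept, "genes_kept": len(genes),
            "threshold": sel.threshold, "kind": sel.kind}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = read_expression(config.expression_path)
    samples = read_sample_annotation(config.samples_path, config.class_map)
    probes = read_probe_annotation(config.probes_path)
    align_annotations(matrix, samples, probes)
    log.info("loaded %d probes x %d samples", *matrix.shape)

    manifest: dict = {
        "sepsiskit_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_probes": int(matrix.shape[0]),
        "n_samples": int(matrix.shape[1]),
        "stages": {},
    }

    # (a) selections and overlap
    sel_cv = cv_filter(matrix, config.cv_threshold, config.cv_scale)
    manifest["stages"]["cv_filter"] = _write_selection(
        sel_cv, probes, outdir / "selection_cv.tsv", "CV filter")

    sel_f = f_test_selection(matrix, samples, config.f_grouping, config.f_alpha)
    manifest["stages"]["f_test"] = _write_selection(
        sel_f, probes, outdir / "selection_ftest.tsv", "F-test")

    sel_a = per_model_selection(matrix, samples, MODEL_A, config.f_alpha)
    sel_b = per_model_selection(matrix, samples, MODEL_B, config.f_alpha)
    manifest["stages"]["model_a_selection"] = _write_selection(
        sel_a, probes, outdir / "selection_modelA.tsv", "model A selection")
    manifest["stages"]["model_b_selection"] = _write_selection(
        sel_b, probes, outdir / "selection_modelB.tsv", "model B selection")

    overlap = collapse_and_overlap(sel_a, sel_b, probes)
    manifest["stages"]["overlap"] = overlap.counts()
    with open(outdir / "overlap.json", "w") as handle:
        json.dump(overlap.counts(), handle, indent=2, sort_keys=True)

    # (b) concordance
    if sel_a.n_probes_kept == 0 and sel_b.n_probes_kept == 0:
        log.warning("no significant probes in either model; concordance skipped")
        manifest["stages"]["concordance"] = {"skipped": "no significant probes"}
        report = None
    else:
        report = model_concordance(matrix, samples, config.f_alpha,
                                   config.universe_rule)
        report.per_timepoint.to_csv(outdir / "concordance.tsv", sep="\t")
        manifest["stages"]["concordance"] = {
            "per_timepoint_r": {t: float(r) for t, r in
                                report.per_timepoint["r"].items()},
            "max_change_r": report.max_change_r,
            "max_change_r2": report.max_change_r2,
            "universe_rule": report.universe_rule,
            "n_universe": int(len(report.universe)),
        }

    # (c) DFR per model on its own significant set
    dfr_rows = []
    group_rows = []
    for model, sel in ((MODEL_A, sel_a), (MODEL_B, sel_b)):
        if sel.n_probes_kept == 0:
            log.warning("no significant probes for %s; DFR skipped", model)
            continue
        ref = build_reference(matrix, samples, sel.kept)
        scores = dfr_scores(matrix, ref, config.dfr_variant)
        scores.insert(0, "universe_model", model)
        dfr_rows.append(scores)
        groups = group_dfr(matrix, samples, ref, config.dfr_variant)
        groups.insert(0, "universe_model", model)
        group_rows.append(groups)
    if dfr_rows:
        pd.concat(dfr_rows).to_csv(outdir / "dfr_samples.tsv", sep="\t")
        group_table = pd.concat(group_rows)
        group_table.to_csv(outdir / "dfr_groups.tsv", sep="\t", index=False)
        manifest["stages"]["dfr"] = {
            "n_universes": len(dfr_rows),
            "variant": config.dfr_variant,
        }
    else:
        manifest["stages"]["dfr"] = {"skipped": "no significant probes"}

    # (d) class prediction with permutation null
    pred = permutation_pvalue(
        matrix, samples,
        n_permutations=config.n_permutations,
        seed=config.seed,
        selector_alpha=config.f_alpha,
        reselect_per_fold=config.reselect_per_fold,
    )
    pred.predictions.to_csv(outdir / "prediction_calls.tsv", sep="\t")
    manifest["stages"]["class_prediction"] = {
        "misclassification_rate": pred.observed_rate,
        "p_value": pred.p_value,
        "n_permutations": pred.n_permutations,
    }

    # (e) gene-set enrichment / activation
    if config.gene_sets_path:
        gene_sets = read_gene_sets(config.gene_sets_path)
        universe = set(probes["gene_symbol"].dropna()) - {""}
        significant = sel_f.gene_symbols(probes)
        gene_changes = None
        if report is not None:
            first_tp = report.per_timepoint.index[0]
            gene_changes = gene_level_change(report.profiles_b[first_tp], probes)
        table = enrichment_table(gene_sets, significant, universe,
                                 gene_changes, config.fold_threshold)
        table.to_csv(outdir / "enrichment.tsv", sep="\t")
        manifest["stages"]["enrichment"] = {"n_sets": len(table)}

    # (f) heat-map ordering
    if config.write_cluster_order and sel_cv.n_probes_kept >= 2:
        order = cluster_order(matrix, sel_cv.kept)
        with open(outdir / "cluster_order_probes.txt", "w") as handle:
            handle.write("\n".join(map(str, order["probe_order"])) + "\n")
        with open(outdir / "cluster_order_samples.txt", "w") as handle:
            handle.write("\n".join(map(str, order["sample_order"])) + "\n")
        manifest["stages"]["cluster_order"] = {
            "n_probes_ordered": len(order["probe_order"]),
            "n_constant_probes": len(order["constant_probes"]),
        }

    with open(outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True, default=float)
    log.info("report bundle written to %s", outdir)
    return manifest
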