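"""End-to-end pipeline driver: configuration, stage sequencing, provenance.

``run_pipeline`` executes simulate -> preprocess -> differential expression
-> clustering -> target consensus -> IHC panel on synthetic inputs (or a
user-supplied expression matrix) and writes a manifest JSON listing every
output with its stage, the seed, and a content hash, so two runs with the
same configuration are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__, io
from .clustering import SignatureClusterer, cluster_composition, export_newick
from .diffexp import differential_expression, results_to_frame, select_signature
from .errors import ConfigError, ValidationError
from .ihc import NegativeMarkerPanel, case_positivity, marker_table
from .preprocess import ArrayPreprocessor, RunStandardizer
from .simulate import (
    CleavageSimConfig,
    ExpressionSimConfig,
    IHCCohortSimConfig,
    TargetSimConfig,
    gen_expression,
    gen_gene_annotations,
    gen_gene_expression,
    gen_ihc_cohort,
    gen_target_tables,
    gen_truth_map,
    gene_universe,
)
from .targets import ConsensusConfig, cleavage_subset, consensus_genes, overlap_stats, union_targets
from .types import ExpressionMatrix, PrevalenceAssumptions, Stage

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "output_dir": "basalmir_results",
    "simulate": {
        "expression": {},  # overrides for ExpressionSimConfig
        "targets": {},  # overrides for TargetSimConfig
        "cleavage": {},  # overrides for CleavageSimConfig
        "ihc": {},  # overrides for IHCCohortSimConfig
    },
    "preprocess": {
        "intensity_threshold": 150.0,
        "standardize_within": "run",
    },
    "diffexp": {
        "top_n_basal": 75,
        "top_n_brca1": 100,
        "alpha": 0.05,
    },
    "clustering": {
        "n_clusters": 2,
    },
    "targets": {
        "min_support": 3,
        "require_opposite_mrna_direction": True,
        "alpha": 0.05,
    },
    "ihc": {
        "panel": ["FOXP1", "CCND1", "NRP1"],
        "k": 2,
        "prev_mutation": 0.02,
        "prev_basal": 0.15,
        "prev_basal_given_mutation": 0.69,
    },
}


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {here!r}")
        if isinstance(defaults[key], Mapping) and not here.startswith("simulate."):
            if not isinstance(value, Mapping):
                raise ConfigError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def validate_config(source: str | Path | Mapping[str, Any] | None = None) -> dict:
    """Load a YAML (key: value) configuration, fill defaults, reject
    unknown keys. ``None`` or an empty file yields all defaults."""
    if source is None:
        raw: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"configuration file {path} does not exist")
        loaded = yaml.safe_load(path.read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"{path}: configuration must be a mapping")
        raw = loaded
    config = _merge(DEFAULTS, raw)
    for section, cls in (
        ("expression", ExpressionSimConfig),
        ("targets", TargetSimConfig),
        ("cleavage", CleavageSimConfig),
        ("ihc", IHCCohortSimConfig),
    ):
        overrides = config["simulate"][section]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in simulate.{section}"
            )
    return config


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _spawn_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1000003 + offset) % (2**31 - 1)


def run_pipeline(config: Mapping[str, Any] | str | Path | None = None, output_dir=None) -> dict:
    """Execute every stage on seeded synthetic inputs and return the
    artifact manifest."""
    cfg = validate_config(config)
    seed = int(cfg["seed"])
    out_dir = Path(output_dir if output_dir is not None else cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "pipeline_version": __version__,
        "seed": seed,
        "outputs": [],
    }

    def record(path: Path, stage: str, params: Mapping[str, Any] | None = None) -> None:
        manifest["outputs"].append(
            {
                "path": path.name,
                "stage": stage,
                "params": dict(params or {}),
                "sha256": _sha256(path),
            }
        )

    # -- simulate ----------------------------------------------------------
    expr_cfg = ExpressionSimConfig(**{**cfg["simulate"]["expression"], "seed": _spawn_seed(seed, 1)})
    raw, annotations, truth = gen_expression(expr_cfg)
    io.write_expression_matrix(raw, out_dir / "expression_raw.tsv")
    io.write_annotations(annotations, out_dir / "annotations.tsv")
    record(out_dir / "expression_raw.tsv", "simulate")
    record(out_dir / "annotations.tsv", "simulate")

    # -- preprocess --------------------------------------------------------
    pre = ArrayPreprocessor(intensity_threshold=float(cfg["preprocess"]["intensity_threshold"]))
    normalized = pre.fit_transform(raw)
    standardizer = RunStandardizer(annotations, within=cfg["preprocess"]["standardize_within"])
    standardized = standardizer.fit(normalized).transform(normalized)
    io.write_expression_matrix(normalized, out_dir / "expression_quantile.tsv")
    io.write_expression_matrix(standardized, out_dir / "expression_standardized.tsv")
    record(out_dir / "expression_quantile.tsv", "preprocess", cfg["preprocess"])
    record(out_dir / "expression_standardized.tsv", "preprocess", cfg["preprocess"])

    # -- differential expression ------------------------------------------
    de_basal = differential_expression(
        normalized, annotations, (("basal_sporadic", "basal_brca1"), ("luminal",))
    )
    de_brca1 = differential_expression(
        normalized, annotations, ("basal_brca1", "basal_sporadic")
    )
    frame_basal = results_to_frame(de_basal)
    frame_brca1 = results_to_frame(de_brca1)
    frame_basal.to_csv(out_dir / "de_basal_vs_luminal.tsv", sep="\t", index=False)
    frame_brca1.to_csv(out_dir / "de_brca1_vs_sporadic.tsv", sep="\t", index=False)
    record(out_dir / "de_basal_vs_luminal.tsv", "diffexp", cfg["diffexp"])
    record(out_dir / "de_brca1_vs_sporadic.tsv", "diffexp", cfg["diffexp"])

    alpha = float(cfg["diffexp"]["alpha"])
    signature = select_signature(
        [de_basal, de_brca1],
        [int(cfg["diffexp"]["top_n_basal"]), int(cfg["diffexp"]["top_n_brca1"])],
    )

    # -- clustering --------------------------------------------------------
    basal_samples = [
        a.sample_id for a in annotations if a.group in ("basal_sporadic", "basal_brca1")
    ]
    sig_em = standardized.frame.loc[signature, basal_samples]
    clusterer = SignatureClusterer(n_clusters=int(cfg["clustering"]["n_clusters"]))
    clusterer.fit(ExpressionMatrix(sig_em, Stage.STANDARDIZED))
    (out_dir / "dendrogram.nwk").write_text(export_newick(clusterer.dendrogram_) + "\n")
    composition = cluster_composition(clusterer.label_map_, annotations)
    composition.to_csv(out_dir / "cluster_composition.tsv", sep="\t")
    assignments = "\n".join(f"{s}\t{l}" for s, l in sorted(clusterer.label_map_.items()))
    (out_dir / "cluster_assignments.tsv").write_text("sample_id\tcluster\n" + assignments + "\n")
    record(out_dir / "dendrogram.nwk", "clustering", cfg["clustering"])
    record(out_dir / "cluster_composition.tsv", "clustering", cfg["clustering"])
    record(out_dir / "cluster_assignments.tsv", "clustering", cfg["clustering"])

    # -- target consensus --------------------------------------------------
    de_mirnas = {
        r.feature_id: r.direction for r in de_brca1 if r.p_adjusted < alpha
    }
    if not de_mirnas:
        raise ValidationError("no differentially expressed miRNAs for target analysis")
    target_cfg = TargetSimConfig(**{**cfg["simulate"]["targets"], "seed": _spawn_seed(seed, 2)})
    truth_map, consensus_direction = gen_truth_map(target_cfg, de_mirnas)
    tables = gen_target_tables(target_cfg, sorted(de_mirnas), truth_map)
    for i, table in enumerate(tables):
        io.write_target_table(table, out_dir / f"targets_source{i + 1}.tsv")
        record(out_dir / f"targets_source{i + 1}.tsv", "targets")
    union = union_targets(tables)
    consensus_cfg = ConsensusConfig(
        min_support=int(cfg["targets"]["min_support"]),
        require_opposite_mrna_direction=bool(cfg["targets"]["require_opposite_mrna_direction"]),
    )
    consensus = consensus_genes(union, de_mirnas, consensus_cfg)

    cleav_cfg = CleavageSimConfig(**{**cfg["simulate"]["cleavage"], "seed": _spawn_seed(seed, 3)})
    gene_ann = gen_gene_annotations()
    mrna_raw, cleavage_truth = gen_gene_expression(
        cleav_cfg, consensus_direction, gene_ann, gene_universe(target_cfg)
    )
    mrna_norm = ArrayPreprocessor(intensity_threshold=0.0).fit_transform(mrna_raw)
    mrna_de = differential_expression(mrna_norm, gene_ann, ("basal_brca1", "basal_sporadic"))
    mrna_map = {r.feature_id: (r.p_adjusted, r.direction) for r in mrna_de}
    consensus = cleavage_subset(consensus, mrna_map, consensus_cfg, alpha=float(cfg["targets"]["alpha"]))
    stats = overlap_stats(consensus)
    consensus_rows = [
        "\t".join(
            [
                g.gene_id,
                str(g.support),
                g.predicted_protein_direction,
                str(g.in_both_lists),
                str(g.cleavage_flag),
            ]
        )
        for g in consensus
    ]
    (out_dir / "consensus_genes.tsv").write_text(
        "gene_id\tsupport\tpredicted_protein_direction\tin_both_lists\tcleavage_flag\n"
        + "\n".join(consensus_rows)
        + "\n"
    )
    (out_dir / "target_stats.json").write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    record(out_dir / "consensus_genes.tsv", "targets", cfg["targets"])
    record(out_dir / "target_stats.json", "targets", cfg["targets"])

    # -- IHC panel ---------------------------------------------------------
    ihc_cfg = IHCCohortSimConfig(**{**cfg["simulate"]["ihc"], "seed": _spawn_seed(seed, 4)})
    records, ihc_truth = gen_ihc_cohort(ihc_cfg)
    io.write_ihc_table(records, out_dir / "ihc_records.tsv")
    record(out_dir / "ihc_records.tsv", "ihc")
    markers = sorted({r.marker for r in records})
    comparisons = marker_table(records, markers)
    comparisons.to_csv(out_dir / "ihc_marker_comparisons.tsv", sep="\t")
    record(out_dir / "ihc_marker_comparisons.tsv", "ihc")

    assumptions = PrevalenceAssumptions(
        p_mutation_in_breast_cancer=float(cfg["ihc"]["prev_mutation"]),
        p_basal_phenotype=float(cfg["ihc"]["prev_basal"]),
        p_basal_given_mutation=float(cfg["ihc"]["prev_basal_given_mutation"]),
    )
    panel = NegativeMarkerPanel(markers=tuple(cfg["ihc"]["panel"]), k=int(cfg["ihc"]["k"]))
    grid = case_positivity(records)
    panel.fit(grid)
    result = panel.evaluate(grid, grid["truth_group"], assumptions=assumptions)
    panel_json = {
        "rule": {"markers": list(result.rule.markers), "k": result.rule.k},
        "confusion": {"tp": result.tp, "fp": result.fp, "tn": result.tn, "fn": result.fn},
        "n_excluded": result.n_excluded,
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "cohort_ppv": result.cohort_ppv,
        "cohort_npv": result.cohort_npv,
        "derived_prevalence": result.derived_prevalence,
        "adjusted_ppv": result.adjusted_ppv,
        "adjusted_npv": result.adjusted_npv,
        "assumptions": dataclasses.asdict(result.assumptions),
    }
    (out_dir / "ihc_panel.json").write_text(json.dumps(panel_json, indent=2, sort_keys=True) + "\n")
    record(out_dir / "ihc_panel.json", "ihc", cfg["ihc"])

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d outputs in %s", len(manifest["outputs"]), out_dir)
    return manifest
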