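"""End-to-end orchestration of the synthetic analysis run.

Stages, in dependency order: simulate the study matrix and the reference
panels; derive cell-type signatures; score them per sample (ssGSEA);
associate scores with the dual-positive phenotype (IC + permutation p);
cluster the study samples by NMF; build the oncogene-module state map and
project the study samples onto it; differential expression between the
dual-positive and type II groups; gated population fractions, ddCT fold
changes and the engraftment-count comparison.

Stages communicate through files in the output directory, and every
artifact is recorded in a JSON manifest with its SHA-256 hash and the
stage parameters, so a rerun with the same config is byte-identical and
verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import simulate
from .association import associate_collection, results_table
from .diffexp import differential_expression
from .io import (
    FLOAT_FORMAT,
    ValidationError,
    write_annotation,
    write_expression,
    write_gmt,
)
from .nmf import assign_clusters, fit_nmf
from .oncogps import build_map, project_samples, projections_table, save_map
from .quantify import (
    compare_fractions,
    fold_changes,
    gate_cells,
    single_marker_gatespec,
    two_marker_gatespec,
)
from .signatures import derive_all
from .ssgsea import score_collection

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "n_top": 100,
    "ssgsea_weight": 0.75,
    "n_permutations": 1000,
    "nmf": {"rank": 3, "n_restarts": 20},
    "oncogps": {"k_nodes": 9, "n_states": 4, "nmf_restarts": 5},
    "kras_panel": {"n_cell_lines": 60, "module_size": 1000, "n_states": 3},
    "gating": {
        "n_cells": 100000,
        "dualpos_fraction": 0.026,
        "notch_positive_fraction": 0.5035,
    },
    "qpcr": {
        "true_fold_changes": {"Rage": 4.0, "Aqp5": 2.0, "Sftpc": 1.5},
        "noise_sd": 0.0,
    },
    "engraftment": {
        "Rag1KO": {"dualpos": [7, 10], "typeII": [2, 10]},
        "NOD_SCID": {"dualpos": [8, 9], "typeII": [0, 8]},
    },
}

REQUIRED_KEYS = ("seed", "n_top", "ssgsea_weight", "n_permutations", "nmf", "oncogps")


class ConfigError(ValueError):
    """Configuration fails validation before any compute."""


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the committed defaults."""
    config = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in user.items():
            if isinstance(value, dict) and isinstance(config.get(key), dict):
                config[key].update(value)
            else:
                config[key] = value
    validate_config(config)
    return config


def validate_config(config: dict[str, Any]) -> None:
    missing = [k for k in REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigError(f"config missing keys: {missing}")
    if not isinstance(config["seed"], int):
        raise ConfigError("seed must be an integer")
    if config["n_top"] < 1:
        raise ConfigError("n_top must be >= 1")
    if config["n_permutations"] < 100:
        raise ConfigError("n_permutations must be >= 100")
    if config["nmf"]["rank"] < 1:
        raise ConfigError("nmf rank must be >= 1")
    if config["oncogps"]["k_nodes"] < 2:
        raise ConfigError("oncogps k_nodes must be >= 2")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class Manifest:
    out_dir: Path
    config: dict[str, Any]
    artifacts: list[dict[str, Any]] = field(default_factory=list)

    def record(self, stage: str, path: Path, **params: Any) -> None:
        self.artifacts.append(
            {
                "stage": stage,
                "path": str(path.relative_to(self.out_dir)),
                "sha256": _sha256(path),
                "params": params,
            }
        )

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        path.write_text(
            json.dumps(
                {"config": self.config, "artifacts": self.artifacts},
                indent=2,
                sort_keys=True,
            )
        )
        return path


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)
    return path


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> Path:
    """Run every stage; returns the path of the JSON manifest."""
    validate_config(config)
    out_dir = Path(out_dir)
    if not out_dir.parent.exists():
        raise ConfigError(f"parent of output dir does not exist: {out_dir.parent}")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(out_dir, config)
    seed = config["seed"]

    logger.info("stage simulate_study")
    matrix, annotation = simulate.simulate_study(simulate.default_study_design(seed=seed))
    manifest.record(
        "simulate_study", write_expression(matrix, out_dir / "study_matrix.tsv"), seed=seed
    )
    manifest.record(
        "simulate_study", write_annotation(annotation, out_dir / "study_annotation.tsv")
    )

    logger.info("stage simulate_panels")
    panels = simulate.simulate_reference_panels(seed=seed)
    for name, (panel_matrix, panel_ann) in panels.items():
        manifest.record(
            "simulate_panels",
            write_expression(panel_matrix, out_dir / f"panel_{name}.tsv"),
            panel=name,
        )
        manifest.record(
            "simulate_panels",
            write_annotation(panel_ann, out_dir / f"panel_{name}_annotation.tsv"),
            panel=name,
        )

    logger.info("stage signatures")
    signatures = derive_all(panels, n_top=config["n_top"])
    manifest.record(
        "signatures",
        write_gmt(signatures, out_dir / "signatures.gmt"),
        n_top=config["n_top"],
    )

    logger.info("stage ssgsea")
    scores = score_collection(matrix, signatures, weight=config["ssgsea_weight"])
    scores_df = scores.scores.copy()
    scores_df.index.name = "set_name"
    manifest.record(
        "ssgsea",
        _write_tsv(scores_df, out_dir / "ssgsea_scores.tsv", index=True),
        weight=config["ssgsea_weight"],
    )
    minmax_df = scores.minmax_normalized().scores.copy()
    minmax_df.index.name = "set_name"
    manifest.record(
        "ssgsea",
        _write_tsv(minmax_df, out_dir / "ssgsea_scores_minmax.tsv", index=True),
        weight=config["ssgsea_weight"],
        normalized=True,
    )

    logger.info("stage association")
    phenotype = annotation.indicator("dualpos")
    associations = associate_collection(
        scores, phenotype, n_permutations=config["n_permutations"], seed=seed
    )
    manifest.record(
        "association",
        _write_tsv(results_table(associations), out_dir / "ic_associations.tsv"),
        target="dualpos",
        n_permutations=config["n_permutations"],
    )

    logger.info("stage nmf")
    model = fit_nmf(
        matrix,
        rank=config["nmf"]["rank"],
        n_restarts=config["nmf"]["n_restarts"],
        seed=seed,
    )
    w_df = model.W.copy()
    w_df.index.name = "gene_id"
    h_df = model.H.copy()
    h_df.index.name = "factor"
    clusters = assign_clusters(model)
    clusters_df = pd.DataFrame(
        {"sample_id": list(clusters), "factor": list(clusters.values())}
    )
    manifest.record("nmf", _write_tsv(w_df, out_dir / "nmf_W.tsv", index=True), **config["nmf"])
    manifest.record("nmf", _write_tsv(h_df, out_dir / "nmf_H.tsv", index=True), **config["nmf"])
    manifest.record("nmf", _write_tsv(clusters_df, out_dir / "nmf_clusters.tsv"))
    objective_path = out_dir / "nmf_objective.txt"
    objective_path.write_text(
        "\n".join(FLOAT_FORMAT % v for v in model.objective_trace) + "\n"
    )
    manifest.record("nmf", objective_path)

    logger.info("stage oncogps")
    kras = simulate.simulate_kras_panel(seed=seed, **config["kras_panel"])
    gps_map = build_map(
        kras.matrix,
        kras.module,
        k_nodes=config["oncogps"]["k_nodes"],
        n_states=config["oncogps"]["n_states"],
        nmf_restarts=config["oncogps"]["nmf_restarts"],
        seed=seed,
    )
    manifest.record(
        "oncogps", save_map(gps_map, out_dir / "oncogps_map.json"), **config["oncogps"]
    )
    projections = project_samples(gps_map, matrix, seed=seed)
    manifest.record(
        "oncogps",
        _write_tsv(projections_table(projections), out_dir / "oncogps_projections.tsv"),
    )

    logger.info("stage diffexp")
    de = differential_expression(matrix, annotation, "dualpos", "typeII")
    manifest.record(
        "diffexp",
        _write_tsv(de, out_dir / "de_dualpos_vs_typeII.tsv"),
        group_a="dualpos",
        group_b="typeII",
    )

    logger.info("stage quantification")
    gating = config["gating"]
    dp_cells = simulate.simulate_cells(
        simulate.dual_positive_spec(
            gating["dualpos_fraction"], n_cells=gating["n_cells"], seed=seed
        )
    )
    dp_pops = gate_cells(dp_cells, two_marker_gatespec())
    manifest.record(
        "quantification",
        _write_tsv(dp_pops, out_dir / "gated_dualpos_populations.tsv", index=True),
        **{k: v for k, v in gating.items() if k != "notch_positive_fraction"},
    )
    notch_cells = simulate.simulate_cells(
        simulate.notch_reporter_spec(
            gating["notch_positive_fraction"], n_cells=gating["n_cells"], seed=seed + 1
        )
    )
    notch_pops = gate_cells(notch_cells, single_marker_gatespec())
    manifest.record(
        "quantification",
        _write_tsv(notch_pops, out_dir / "gated_notch_populations.tsv", index=True),
        notch_positive_fraction=gating["notch_positive_fraction"],
    )

    qpcr = config["qpcr"]
    ct_table = simulate.simulate_ct_table(
        qpcr["true_fold_changes"], noise_sd=qpcr["noise_sd"], seed=seed
    )
    manifest.record("quantification", _write_tsv(ct_table, out_dir / "ct_table.tsv"))
    manifest.record(
        "quantification", _write_tsv(fold_changes(ct_table), out_dir / "fold_changes.tsv")
    )

    engraftment_rows = []
    for background, arms in config["engraftment"].items():
        odds_ratio, p = compare_fractions(tuple(arms["dualpos"]), tuple(arms["typeII"]))
        engraftment_rows.append(
            {
                "background": background,
                "dualpos": f"{arms['dualpos'][0]}/{arms['dualpos'][1]}",
                "typeII": f"{arms['typeII'][0]}/{arms['typeII'][1]}",
                "odds_ratio": odds_ratio,
                "fisher_p": p,
            }
        )
    manifest.record(
        "quantification",
        _write_tsv(pd.DataFrame(engraftment_rows), out_dir / "engraftment_comparison.tsv"),
    )

    path = manifest.write()
    logger.info("pipeline complete: %d artifacts", len(manifest.artifacts))
    return path
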