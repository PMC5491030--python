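"""End-to-end orchestration: simulate/load -> waves -> regression -> clusters.

A run writes a self-describing bundle to the output directory: the manifest
(seeds, config echo, versions), the analysis dataset, per-wave estimates and
serialized models, the regression table (TSV + JSON), the salience table
(TSV + JSON), the full Cohen's-d matrix and the cluster assignments.  Every
numeric table has a JSON twin.  Runs are byte-identical given a master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from ._seeds import derive_seed
from .catalog import BehaviorCatalog, default_catalog
from .cluster import (
    TwoStageClusterer,
    build_cluster_matrix,
    engagement_ordering,
    render_salience_table,
    salience_profile,
)
from .data import assemble_blocks, load_raw, standardize
from .network import MLPWaveRegressor, run_prediction_waves
from .regression import hierarchical_regression, render_regression_table
from .simulate import SimulationConfig, default_study_config, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Exactly one of ``input_path`` / ``simulation`` must be present."""

    out_dir: str | Path
    input_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    seed: int = 0
    catalog: BehaviorCatalog | None = None
    network_params: dict = field(default_factory=dict)
    cluster_params: dict = field(default_factory=dict)
    feature_mode: str = "predictors_plus_estimate"
    salience_threshold: float = 0.50
    holdout_estimates: bool = False

    def validate(self) -> "RunConfig":
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError("provide exactly one of input_path or simulation")
        return self


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the artifact bundle; returns file paths."""
    config.validate()
    catalog = config.catalog or default_catalog()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    t0 = time.time()

    # -- stage: data -----------------------------------------------------
    if config.simulation is not None:
        sim_seed = derive_seed(config.seed, "simulate")
        raw, truth = generate_dataset(config.simulation, seed=sim_seed, catalog=catalog)
        paths["dataset"] = out / "dataset.csv"
        raw.to_csv(paths["dataset"], catalog)
        paths["truth"] = out / "truth.json"
        _dump_json(
            paths["truth"],
            {
                "group_labels": truth.group_labels.tolist(),
                "planted_increments": truth.planted_increments,
            },
        )
    else:
        raw = load_raw(config.input_path, catalog)
    logger.info("stage=data n=%d behaviors=%d elapsed=%.1fs", raw.n_participants, len(catalog), time.time() - t0)

    # -- stage: standardize + blocks ------------------------------------
    std = standardize(raw, catalog)
    blocks = assemble_blocks(std, catalog)
    y = std.health_index.to_numpy()

    # -- stage: waves ----------------------------------------------------
    net = MLPWaveRegressor(**config.network_params)
    waves = run_prediction_waves(
        blocks,
        y,
        base_estimator=net,
        random_state=derive_seed(config.seed, "waves"),
        holdout_estimates=config.holdout_estimates,
    )
    paths["waves"] = out / "waves.json"
    _dump_json(
        paths["waves"],
        {
            w.wave_name: {
                "r_with_target": w.r_with_target,
                "estimates": np.round(w.estimates, 10).tolist(),
                "epochs": w.model.n_iter_,
                "best_restart": w.model.best_restart_,
            }
            for w in waves
        },
    )
    paths["models"] = out / "models.json"
    _dump_json(paths["models"], {w.wave_name: w.model.to_json_dict() for w in waves})
    logger.info("stage=waves n_waves=%d elapsed=%.1fs", len(waves), time.time() - t0)

    # -- stage: regression ----------------------------------------------
    regression = hierarchical_regression(waves, y)
    paths["table2_json"] = out / "regression.json"
    _dump_json(paths["table2_json"], regression.to_json_dict())
    paths["table2_tsv"] = out / "regression.tsv"
    paths["table2_tsv"].write_text(render_regression_table(regression), encoding="utf-8")

    # -- stage: clustering ----------------------------------------------
    features = build_cluster_matrix(blocks, waves["saturated"], config.feature_mode)
    clusterer = TwoStageClusterer(
        random_state=derive_seed(config.seed, "cluster"), **config.cluster_params
    )
    solution = engagement_ordering(clusterer.fit(features).solution(), y)
    profile = salience_profile(solution, std, blocks, config.salience_threshold)
    paths["clusters"] = out / "clusters.json"
    _dump_json(
        paths["clusters"],
        {
            "k": solution.k,
            "group_sizes": list(solution.group_sizes),
            "assignments": solution.assignments.tolist(),
            "engagement_labels": {str(g): solution.label_of(g) for g in range(solution.k)},
            "engagement_d": {solution.label_of(g): solution.engagement_d.get(g) for g in range(solution.k)},
        },
    )
    paths["table3_json"] = out / "salience.json"
    _dump_json(paths["table3_json"], profile.to_json_dict())
    paths["table3_tsv"] = out / "salience.tsv"
    paths["table3_tsv"].write_text(render_salience_table(profile), encoding="utf-8")
    paths["d_matrix"] = out / "d_matrix.tsv"
    paths["d_matrix"].write_text(render_salience_table(profile, full=True), encoding="utf-8")
    logger.info("stage=cluster k=%d sizes=%s elapsed=%.1fs", solution.k, solution.group_sizes, time.time() - t0)

    # -- manifest --------------------------------------------------------
    paths["manifest"] = out / "manifest.json"
    _dump_json(
        paths["manifest"],
        {
            "milieu_version": __version__,
            "seed": config.seed,
            "stage_seeds": {
                "simulate": derive_seed(config.seed, "simulate"),
                "waves": derive_seed(config.seed, "waves"),
                "cluster": derive_seed(config.seed, "cluster"),
            },
            "input": str(config.input_path) if config.input_path else None,
            "simulation": config.simulation.to_dict() if config.simulation else None,
            "network_params": config.network_params,
            "cluster_params": config.cluster_params,
            "feature_mode": config.feature_mode,
            "salience_threshold": config.salience_threshold,
            "n_participants": raw.n_participants,
        },
    )
    return paths


def default_run(out_dir: str | Path, seed: int = 0, **overrides) -> dict[str, Path]:
    """Simulate the default study design and analyze it end to end."""
    cfg = RunConfig(out_dir=out_dir, simulation=default_study_config(), seed=seed, **overrides)
    return run_pipeline(cfg)
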