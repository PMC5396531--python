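"""End-to-end orchestration: simulate/load -> partition -> classify -> model
-> atrophy -> correlate, with deterministic seeding and a JSON report.

Every random stage derives its own child seed from the master seed by stable
hashing of the stage name, so re-running a configuration reproduces all
outputs bit-identically and stages can be re-ordered without changing their
streams.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from connectolapse import io as cio
from connectolapse.io import LongDataset, average_connectomes
from connectolapse.models import run_subtype_models
from connectolapse.partition import ModulePartition, consensus_partition
from connectolapse.simulate import SimulationConfig, generate_cohort
from connectolapse.subtypes import (
    ANALYSED_SUBTYPES,
    count_connection_level_pairs,
    enumerate_subtype_connections,
    subtype_strength_table,
)
from connectolapse.topology import (
    anova_subtypes,
    compute_atrophy_table,
    length_atrophy_correlation,
    shortest_paths,
    to_length_matrix,
    tukey_kramer,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_dataset", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stable across stage re-ordering)."""
    return (int(master_seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either ``data_dir`` points at an existing dataset (atlas.tsv, cohort.csv,
    connectomes/sub-*_visit-*.csv) or ``simulation`` holds keyword arguments
    for :class:`~connectolapse.simulate.SimulationConfig`.
    """

    data_dir: str | None = None
    simulation: dict = field(default_factory=dict)
    gammas: tuple[float, ...] = (0.6, 1.0, 1.7)
    primary_gamma: float = 1.0
    n_runs: int = 100
    tau: float = 0.5
    consensus: str = "agreement"
    partition_visits: str = "baseline"  # or "all"
    transform: str = "logistic"
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")
        if any(g <= 0 for g in self.gammas) or self.primary_gamma <= 0:
            raise ValueError("gamma values must be positive")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update(overrides)
        if "gammas" in data:
            data["gammas"] = tuple(data["gammas"])
        return cls(**data)


def load_dataset(data_dir: str | Path) -> LongDataset:
    """Load a dataset written by the simulate stage (or hand-assembled)."""
    data_dir = Path(data_dir)
    atlas = cio.read_region_table(data_dir / "atlas.tsv")
    cohort = cio.read_cohort_table(data_dir / "cohort.csv")
    observations = [
        cio.read_connectome(p, atlas) for p in sorted((data_dir / "connectomes").glob("sub-*_visit-*.csv"))
    ]
    return LongDataset(atlas=atlas, observations=observations, cohort=cohort)


def write_dataset(dataset: LongDataset, truth, data_dir: str | Path) -> None:
    data_dir = Path(data_dir)
    (data_dir / "connectomes").mkdir(parents=True, exist_ok=True)
    cio.write_region_table(dataset.atlas, data_dir / "atlas.tsv")
    cio.write_cohort_table(dataset.cohort, data_dir / "cohort.csv")
    for obs in dataset.observations:
        cio.write_connectome(
            obs, data_dir / "connectomes" / f"sub-{obs.subject_id}_visit-{obs.visit}.csv", dataset.atlas
        )
    if truth is not None:
        truth.to_json(data_dir / "ground_truth.json")


def _cortical_average(dataset: LongDataset, visits: str) -> np.ndarray:
    visit_filter = (lambda v: v == 1) if visits == "baseline" else None
    avg = average_connectomes(dataset, visit_filter=visit_filter)
    cortical = dataset.atlas.cortical_ids
    return avg[np.ix_(cortical, cortical)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full analysis; returns (and optionally writes) the report."""
    t0 = time.time()
    report: dict[str, Any] = {"config": {"seed": config.seed, "gammas": list(config.gammas)}}

    # --- stage: data
    if config.data_dir is not None:
        dataset = load_dataset(config.data_dir)
        truth = None
    else:
        sim = SimulationConfig(**{"seed": stage_seed(config.seed, "simulate"), **config.simulation})
        dataset, truth = generate_cohort(sim)
    atlas = dataset.atlas
    report["data"] = {
        "n_regions": atlas.n,
        "n_cortical": int(len(atlas.cortical_ids)),
        "n_striatal": int(len(atlas.striatal_ids)),
        "n_subjects": len(dataset.cohort),
        "n_observations": len(dataset.observations),
    }
    logger.info("data: %s", report["data"])

    # --- stage: partition (+ gamma sensitivity)
    W_cort = _cortical_average(dataset, config.partition_visits)
    cortical_ids = [int(i) for i in atlas.cortical_ids]
    partitions: dict[float, ModulePartition] = {}
    for gamma in sorted(set((*config.gammas, config.primary_gamma))):
        partitions[gamma] = consensus_partition(
            W_cort,
            gamma=gamma,
            n_runs=config.n_runs,
            tau=config.tau,
            seed=stage_seed(config.seed, f"partition-{gamma}"),
            method=config.consensus,
            node_ids=cortical_ids,
        )
    primary = partitions[config.primary_gamma]
    report["partition"] = {
        "module_counts_by_gamma": {str(g): partitions[g].n_modules for g in sorted(partitions)},
        "primary_gamma": config.primary_gamma,
        "n_modules": primary.n_modules,
        "Q": primary.Q,
    }
    logger.info("partition: %s", report["partition"])

    # --- stage: classify
    connections = enumerate_subtype_connections(atlas, primary.assignment)
    subtype_counts = {s.value: 0 for s in ANALYSED_SUBTYPES}
    for conn in connections:
        subtype_counts[conn.subtype.value] += 1
    n_pairs = count_connection_level_pairs(atlas)
    report["classify"] = {"subtype_counts": subtype_counts, "n_region_pairs": n_pairs}
    logger.info("classify: %s", report["classify"])

    # --- stage: model (subtype-level longitudinal contrasts)
    model_df = run_subtype_models(dataset, connections)
    report["model"] = {
        "n_connections": int(len(model_df)),
        "n_gamma_q_significant": int((model_df["gamma_q"] < config.fdr_q).sum()),
        "n_delta_q_significant": int((model_df["delta_q"] < config.fdr_q).sum()),
        "significant_by_subtype": {
            s: {
                "gamma": int(((model_df["subtype"] == s) & (model_df["gamma_q"] < config.fdr_q)).sum()),
                "delta": int(((model_df["subtype"] == s) & (model_df["delta_q"] < config.fdr_q)).sum()),
            }
            for s in subtype_counts
        },
    }
    logger.info("model: %s", report["model"])

    # --- stage: atrophy + path lengths (control baseline average network)
    control_avg = average_connectomes(
        dataset, subject_filter=lambda r: r.group == "control", visit_filter=lambda v: v == 1
    )
    L = shortest_paths(to_length_matrix(control_avg))
    atrophy = compute_atrophy_table(dataset, primary.assignment, L, transform=config.transform)

    # --- stage: correlate
    cross = length_atrophy_correlation(atrophy["L"], atrophy["score_cross"])
    longi = length_atrophy_correlation(atrophy["L"], atrophy["score_long"])
    groups = {
        s.value: atrophy.loc[np.isfinite(atrophy["L"]) & (atrophy["subtype"] == s.value), "L"].to_numpy()
        for s in ANALYSED_SUBTYPES
    }
    groups = {k: v for k, v in groups.items() if v.size >= 2}
    F, df1, df2, p_anova = anova_subtypes(groups)
    tukey = tukey_kramer(groups)
    subtype_mean_L = {k: float(v.mean()) for k, v in groups.items()}
    report["correlate"] = {
        "cross_sectional": {"rho": cross.rho, "p": cross.p, "df": cross.df, "n": cross.n, "n_excluded": cross.n_excluded},
        "longitudinal": {"rho": longi.rho, "p": longi.p, "df": longi.df, "n": longi.n, "n_excluded": longi.n_excluded},
        "anova": {"F": F, "df1": df1, "df2": df2, "p": p_anova},
        "tukey_all_significant": bool((tukey["p_adj"] < 0.05).all()),
        "subtype_mean_path_length": subtype_mean_L,
    }
    assert cross.n + cross.n_excluded == n_pairs, "pair totals do not reconcile"
    logger.info("correlate: %s", report["correlate"])

    report["wall_time_s"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_outputs(out_dir, dataset, truth, partitions, primary, connections, model_df, L, atrophy, tukey, report)
    return report


def _write_outputs(out_dir, dataset, truth, partitions, primary, connections, model_df, L, atrophy, tukey, report):
    atlas = dataset.atlas
    pd.DataFrame(
        {"region": [atlas.regions[r].name for r in sorted(primary.assignment)],
         "module": [primary.assignment[r] for r in sorted(primary.assignment)]}
    ).to_csv(out_dir / "partition.tsv", sep="\t", index=False)
    np.savetxt(out_dir / "agreement.csv", primary.agreement, delimiter=",")
    pd.DataFrame(
        [
            {"connection": c.name, "subtype": c.subtype.value, "n_pairs": len(c.member_pairs)}
            for c in connections
        ]
    ).to_csv(out_dir / "connections.tsv", sep="\t", index=False)
    subtype_strength_table(dataset, connections).to_csv(out_dir / "subtype_strengths.csv", index=False)
    model_df.to_csv(out_dir / "model_results.csv", index=False)
    np.savetxt(out_dir / "path_lengths.csv", L, delimiter=",")
    atrophy.to_csv(out_dir / "atrophy.csv", index=False)
    tukey.to_csv(out_dir / "tukey.csv", index=False)
    if truth is not None:
        truth.to_json(out_dir / "ground_truth.json")
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
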