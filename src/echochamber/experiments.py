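"""Beta-sweep and transient-trajectory harnesses.

A sweep runs ``reps_per_beta`` independent simulations for every value on a
beta grid, collects one measure record per replicate, and aggregates per
beta.  Replicate seeds are ``SeedSequence(root_seed, spawn_key=(beta_index,
replicate))``, so any cell of the sweep is reproducible (and parallelizable)
in isolation.  Aggregate rows are pure functions of the replicate rows and
can always be recomputed from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import run_simulation
from .measures import RECORD_FIELDS, summarize
from .opinion_models import make_model_spec

logger = logging.getLogger(__name__)

#: The full study grid: 51 evenly spaced propensities on [0, 1].
DEFAULT_BETA_GRID = tuple(round(0.02 * i, 2) for i in range(51))


@dataclass
class ExperimentConfig:
    """Configuration of one sweep or trajectory experiment.

    ``reps_per_beta`` defaults to the desk scale of 2,000 replicates per
    grid value; the full-scale study (30,000 per value) is the same
    configuration with a larger count and is a documented long-run mode.
    """

    model: str
    n: int | None = None  # None = the model's default group size
    k: int = 5
    topology: str = "random"
    beta_grid: tuple = DEFAULT_BETA_GRID
    reps_per_beta: int = 2000
    root_seed: int = 0
    max_rounds: int = 1000
    trajectory_rounds: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.beta_grid = tuple(float(b) for b in self.beta_grid)
        if not self.beta_grid:
            raise ValueError("beta grid must be non-empty")
        if any(not 0.0 <= b <= 1.0 for b in self.beta_grid):
            raise ValueError("beta values must lie in [0, 1]")
        if self.reps_per_beta < 1:
            raise ValueError("reps_per_beta must be at least 1")

    def model_spec(self):
        overrides = {"n": self.n} if self.n is not None else None
        return make_model_spec(self.model, overrides)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["beta_grid"] = list(self.beta_grid)
        return d

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load a flat key-value config file (YAML)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class SweepResult:
    """Per-replicate rows plus per-beta aggregates of one sweep."""

    config: ExperimentConfig
    replicates: pd.DataFrame
    aggregates: pd.DataFrame

    def recompute_aggregates(self) -> pd.DataFrame:
        return aggregate_replicates(self.replicates)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.replicates.to_csv(out / "replicates.csv", index=False)
        self.aggregates.to_csv(out / "aggregates.csv", index=False)
        with open(out / "config_echo.json", "w") as fh:
            json.dump(self.config.to_dict(), fh, indent=2)


def replicate_seed(root_seed: int, beta_index: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-replicate seed stream."""
    return np.random.SeedSequence(root_seed, spawn_key=(beta_index, replicate))


def aggregate_replicates(replicates: pd.DataFrame) -> pd.DataFrame:
    """Per-beta aggregate rows, recomputable from the raw rows at any time."""
    rows = []
    for beta, grp in replicates.groupby("beta", sort=True):
        rows.append(
            {
                "beta": beta,
                "n_reps": len(grp),
                "mean_individual_performance": grp["individual_performance"].mean(),
                "collective_performance": grp["collective_good"].mean(),
                "mean_opinion_diversity": grp["opinion_diversity"].mean(),
                "mean_giant_scc_fraction": grp["giant_scc_fraction"].mean(),
                "mean_modularity_newman": grp["modularity_newman"].mean(),
                "mean_modularity_squared": grp["modularity_squared"].mean(),
                "mean_rounds_to_steady": grp["rounds_to_steady"].mean(),
                "n_nonconverged": int((~grp["converged"]).sum()),
            }
        )
    return pd.DataFrame(rows)


def _replicate_row(config, spec, beta, beta_index, rep, record_trajectory=False):
    seed = replicate_seed(config.root_seed, beta_index, rep)
    result = run_simulation(
        spec,
        k=config.k,
        beta=beta,
        topology=config.topology,
        seed=seed,
        max_rounds=config.max_rounds,
        record_trajectory=record_trajectory,
    )
    record = (
        result.trajectory[-1] if record_trajectory else summarize(result.final_state)
    )
    row = {
        "model": spec.name,
        "n": spec.n,
        "k": config.k,
        "beta": beta,
        "replicate": rep,
        **record.to_dict(),
        "rounds_to_steady": result.rounds_to_steady,
        "converged": result.converged,
    }
    return row, result


def run_sweep(config: ExperimentConfig) -> SweepResult:
    """Run the full (beta x replicate) grid and aggregate per beta.

    Non-converged runs (round cap hit) are recorded like any other row and
    counted in the aggregates; they are never dropped.
    """
    spec = config.model_spec()
    rows = []
    for bi, beta in enumerate(config.beta_grid):
        for rep in range(config.reps_per_beta):
            row, result = _replicate_row(config, spec, beta, bi, rep)
            rows.append(row)
            if (rep + 1) % 100 == 0:
                logger.info(
                    "sweep %s beta=%.2f replicate=%d rounds=%d converged=%s",
                    spec.name, beta, rep + 1,
                    result.rounds_to_steady, result.converged,
                )
    replicates = pd.DataFrame(rows)
    result = SweepResult(config, replicates, aggregate_replicates(replicates))
    if config.out_dir:
        result.write(config.out_dir)
    return result


def run_trajectory(config: ExperimentConfig) -> pd.DataFrame:
    """Per-round aggregates for the first ``trajectory_rounds`` rounds.

    Runs continue to steady state; rounds past steadiness repeat the steady
    values (the state no longer changes), so every (beta, round) cell
    averages exactly ``reps_per_beta`` snapshots.
    """
    if config.trajectory_rounds is None:
        raise ValueError("trajectory_rounds must be set for a trajectory run")
    horizon = int(config.trajectory_rounds)
    spec = config.model_spec()
    rows = []
    for bi, beta in enumerate(config.beta_grid):
        for rep in range(config.reps_per_beta):
            seed = replicate_seed(config.root_seed, bi, rep)
            result = run_simulation(
                spec,
                k=config.k,
                beta=beta,
                topology=config.topology,
                seed=seed,
                max_rounds=config.max_rounds,
                record_trajectory=True,
            )
            traj = result.trajectory
            for r in range(horizon + 1):
                record = traj[min(r, len(traj) - 1)]
                rows.append(
                    {
                        "model": spec.name,
                        "beta": beta,
                        "replicate": rep,
                        "round": r,
                        **{
                            f: getattr(record, f)
                            for f in RECORD_FIELDS
                            if f != "round"
                        },
                    }
                )
    per_round = pd.DataFrame(rows)
    agg = (
        per_round.groupby(["beta", "round"], sort=True)
        .agg(
            mean_individual_performance=("individual_performance", "mean"),
            collective_performance=("collective_good", "mean"),
            mean_opinion_diversity=("opinion_diversity", "mean"),
            mean_giant_scc_fraction=("giant_scc_fraction", "mean"),
            mean_modularity_newman=("modularity_newman", "mean"),
            mean_modularity_squared=("modularity_squared", "mean"),
        )
        .reset_index()
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_round.to_csv(out / "trajectory_replicates.csv", index=False)
        agg.to_csv(out / "trajectory_aggregates.csv", index=False)
    return agg
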