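"""CSV/JSON interfaces.

All tables are UTF-8 CSV/TSV with a header row.  Fixed column layouts:

- arrivals:   flock_id, bird_id, timestamp_s, location
- roster:     bird_id, flock_id, sex, age, informed[, feeding_activity,
              transmission_weight]
- diffusions: flock_id, patch_rank, bird_id, latency_s, censored
- edge list:  flock_id, from, to, rate_per_hour   (from = follower)
- strengths:  flock_id, bird_id, out_strength, in_strength
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .networks import BIRD, FLOCK, FollowingNetwork, FollowingNetworkSet
from .oada import DiffusionSet, FitResult, diffusions_from_frame, diffusions_to_frame

ARRIVAL_COLUMNS = [FLOCK, BIRD, "timestamp_s", "location"]
DIFFUSION_COLUMNS = [FLOCK, "patch_rank", BIRD, "latency_s", "censored"]
EDGE_COLUMNS = [FLOCK, "from", "to", "rate_per_hour"]


def write_arrivals_csv(log: pd.DataFrame, path) -> None:
    log[ARRIVAL_COLUMNS].to_csv(path, index=False)


def read_arrivals_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ARRIVAL_COLUMNS, path)
    return df


def write_roster_csv(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, index=False)


def read_roster_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, [BIRD, FLOCK, "sex", "age", "informed"], path)
    df["informed"] = df["informed"].astype(bool)
    return df


def write_diffusions_csv(
    diffusions: DiffusionSet, censor_time_s: float, path
) -> None:
    diffusions_to_frame(diffusions, censor_time_s).to_csv(path, index=False)


def read_diffusions_csv(path, roster: pd.DataFrame) -> DiffusionSet:
    df = pd.read_csv(path)
    _require(df, DIFFUSION_COLUMNS, path)
    return diffusions_from_frame(df, roster)


def write_edge_list_csv(nets: FollowingNetworkSet, path) -> None:
    rows = []
    for flock in sorted(nets):
        net = nets[flock]
        for i, follower in enumerate(net.nodes):
            for j, followed in enumerate(net.nodes):
                if i != j and net.adjacency[i, j] != 0.0:
                    rows.append((flock, follower, followed, net.adjacency[i, j]))
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, index=False)


def read_edge_list_csv(path, roster: pd.DataFrame, observation_hours: float) -> FollowingNetworkSet:
    df = pd.read_csv(path)
    _require(df, EDGE_COLUMNS, path)
    nets: FollowingNetworkSet = {}
    for flock, rgrp in roster.groupby(FLOCK, sort=True):
        nodes = sorted(rgrp[BIRD])
        index = {b: k for k, b in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for _, row in df[df[FLOCK] == flock].iterrows():
            adj[index[row["from"]], index[row["to"]]] = float(row["rate_per_hour"])
        nets[str(flock)] = FollowingNetwork(
            flock=str(flock),
            nodes=nodes,
            adjacency=adj,
            observation_hours=observation_hours,
        )
    return nets


def write_strengths_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_ground_truth_json(scenario, path) -> None:
    Path(path).write_text(json.dumps(scenario.to_dict(), indent=2))


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "spec": {
            "network_type": fit.spec.network_type,
            "scenario": fit.spec.scenario,
            "covariates": list(fit.spec.covariates),
            "random_effects": fit.spec.random_effects,
            "pooling": fit.spec.pooling,
        },
        "s_hat": {str(k): v for k, v in fit.s_hat.items()},
        "s_boundary": {str(k): bool(v) for k, v in fit.s_boundary.items()},
        "beta_hat": fit.beta_hat,
        "variance_hat": fit.variance_hat,
        "loglik": fit.loglik,
        "n_events": fit.n_events,
        "k_params": fit.k_params,
        "aicc": fit.aicc,
        "converged": fit.converged,
        "profile_cis": {
            k: [lo, hi] for k, (lo, hi) in fit.profile_cis.items()
        },
    }


def write_fit_result_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2, default=float))


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
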