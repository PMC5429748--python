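"""Following-event detection and social-network construction.

Arrival logs from a feeder are turned into directed *following events*
(one bird arriving within a short window after an initiator), which are
aggregated into directed weighted following networks whose edge weights
are following rates in followings per hour.  The module also computes
feeding-activity counts (total visits), per-bird transmission weights
(visits scaled to the flock maximum) and the homogeneous comparison
networks in which every within-flock connection is set to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: canonical column names shared by all CSV interfaces
FLOCK, BIRD, TIME, LOCATION = "flock_id", "bird_id", "timestamp_s", "location"

SECONDS_PER_HOUR = 3600.0


@dataclass
class FollowingNetwork:
    """Directed weighted following network for a single flock.

    ``weight(i, j)`` is the rate (followings/hour) at which bird ``i``
    followed bird ``j``; it is independent of ``weight(j, i)``.
    """

    flock: str
    nodes: list[str]
    adjacency: np.ndarray  # (n, n); row = follower, column = followed
    observation_hours: float
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if (self.adjacency < 0).any() or not np.isfinite(self.adjacency).all():
            raise ValueError("edge weights must be finite and nonnegative")
        if np.diag(self.adjacency).any():
            raise ValueError("self-loops are not allowed")
        if self.observation_hours <= 0:
            raise ValueError("observation_hours must be positive")
        self._index = {b: k for k, b in enumerate(self.nodes)}

    def weight(self, follower: str, followed: str) -> float:
        return float(self.adjacency[self._index[follower], self._index[followed]])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(flock=self.flock, observation_hours=self.observation_hours)
        g.add_nodes_from(self.nodes)
        rows, cols = np.nonzero(self.adjacency)
        g.add_weighted_edges_from(
            (self.nodes[r], self.nodes[c], float(self.adjacency[r, c]))
            for r, c in zip(rows, cols)
        )
        return g


#: a set of per-flock networks keyed by flock id
FollowingNetworkSet = dict


def _validated_log(log: pd.DataFrame) -> pd.DataFrame:
    required = {FLOCK, BIRD, TIME}
    missing = required - set(log.columns)
    if missing:
        raise ValueError(f"arrival log is missing columns: {sorted(missing)}")
    if len(log) and not np.isfinite(log[TIME].to_numpy(dtype=float)).all():
        raise ValueError("arrival timestamps must be finite")
    if log.duplicated(subset=[FLOCK, BIRD, TIME]).any():
        raise ValueError("arrival log contains duplicated records")
    return log.sort_values([FLOCK, TIME, BIRD], kind="mergesort")


def detect_following_events(log: pd.DataFrame, window_s: float = 5.0) -> pd.DataFrame:
    """Detect following events in an arrival log.

    An arrival opens a new window (and its bird is the *initiator*) iff no
    arrival in the same flock precedes it by ``window_s`` or less.  Every
    arrival strictly later but within ``window_s`` of the initiator is a
    follower of that initiator.  Two or more arrivals sharing the
    window-opening timestamp form a group arrival without an initiator and
    yield no following events; neither do arrivals that fall inside a
    chain of short gaps but outside the initiator's window.

    Returns a DataFrame with columns flock_id, initiator, follower,
    timestamp_s (the follower's arrival time).
    """
    log = _validated_log(log)
    out: list[tuple[str, str, str, float]] = []
    for flock, grp in log.groupby(FLOCK, sort=False):
        times = grp[TIME].to_numpy(dtype=float)
        birds = grp[BIRD].to_numpy()
        init_time = -np.inf
        init_bird: str | None = None
        prev_time = -np.inf
        for k in range(len(times)):
            t, b = times[k], birds[k]
            if t - prev_time > window_s:
                # window opens here; a tie at the opening time means a
                # group arrival with no initiator
                tied = (k + 1 < len(times)) and (times[k + 1] == t)
                init_time, init_bird = t, (None if tied else b)
            elif init_bird is not None and 0.0 < t - init_time <= window_s:
                out.append((flock, init_bird, b, float(t)))
            prev_time = t
    return pd.DataFrame(out, columns=[FLOCK, "initiator", "follower", TIME])


def count_total_visits(
    log: pd.DataFrame, birds: Iterable[str] | None = None
) -> dict[str, int]:
    """Total number of feeder visits per bird (every arrival counts once).

    ``birds`` optionally fixes the key set; birds absent from the log get 0.
    """
    counts = log[BIRD].value_counts().to_dict() if len(log) else {}
    if birds is not None:
        counts = {b: int(counts.get(b, 0)) for b in birds}
    return {b: int(c) for b, c in counts.items()}


def build_following_networks(
    events: pd.DataFrame,
    observation_hours: float,
    roster: pd.DataFrame,
) -> FollowingNetworkSet:
    """Aggregate following events into per-flock following networks.

    Edge weight a(i, j) = (# events where i followed j) / observation_hours.
    ``roster`` (columns bird_id, flock_id) fixes node sets, so flocks with
    no events still yield all-zero networks.
    """
    if observation_hours <= 0:
        raise ValueError("observation_hours must be positive")
    nets: FollowingNetworkSet = {}
    for flock, rgrp in roster.groupby(FLOCK, sort=True):
        nodes = sorted(rgrp[BIRD])
        index = {b: k for k, b in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        if len(events):
            for _, ev in events[events[FLOCK] == flock].iterrows():
                adj[index[ev["follower"]], index[ev["initiator"]]] += 1.0
        nets[flock] = FollowingNetwork(
            flock=str(flock),
            nodes=nodes,
            adjacency=adj / observation_hours,
            observation_hours=observation_hours,
        )
    return nets


def node_strengths(net: FollowingNetwork) -> dict[str, tuple[float, float]]:
    """Weighted out-/in-strength per bird.

    out-strength(i) = sum_j a(i, j): how often i follows others.
    in-strength(i)  = sum_j a(j, i): how often i is followed, i.e. how
    often i was the initiator.
    """
    out_s = net.adjacency.sum(axis=1)
    in_s = net.adjacency.sum(axis=0)
    return {b: (float(out_s[k]), float(in_s[k])) for k, b in enumerate(net.nodes)}


def transmission_weights(
    visits: Mapping[str, float], flock_of: Mapping[str, str]
) -> dict[str, float]:
    """Per-bird transmission weights: visits scaled to the flock maximum.

    w_i = visits_i / max over i's flock; the most active bird in each
    flock has weight exactly 1.  A flock whose birds all have zero visits
    leaves the weights undefined and raises.
    """
    by_flock: dict[str, float] = {}
    for b, v in visits.items():
        f = flock_of[b]
        by_flock[f] = max(by_flock.get(f, 0.0), float(v))
    bad = sorted(f for f, m in by_flock.items() if m <= 0)
    if bad:
        raise ValueError(f"all-zero visit counts in flock(s) {bad}: weights undefined")
    return {b: float(v) / by_flock[flock_of[b]] for b, v in visits.items()}


def homogeneous_networks(roster: pd.DataFrame) -> FollowingNetworkSet:
    """Comparison networks with every within-flock connection set to 1."""
    if not len(roster):
        raise ValueError("roster is empty")
    nets: FollowingNetworkSet = {}
    for flock, rgrp in roster.groupby(FLOCK, sort=True):
        nodes = sorted(rgrp[BIRD])
        adj = np.ones((len(nodes), len(nodes))) - np.eye(len(nodes))
        nets[flock] = FollowingNetwork(
            flock=str(flock), nodes=nodes, adjacency=adj, observation_hours=1.0
        )
    return nets


def strengths_table(nets: FollowingNetworkSet) -> pd.DataFrame:
    """Long-format out-/in-strength table over a network set."""
    rows = []
    for flock in sorted(nets):
        for b, (o, i) in node_strengths(nets[flock]).items():
            rows.append((flock, b, o, i))
    return pd.DataFrame(rows, columns=[FLOCK, BIRD, "out_strength", "in_strength"])
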