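"""Synthetic flock data with known parameters.

Generates everything the analysis pipeline consumes — bird rosters,
pre-training arrival logs (with planted, recorded following events),
following networks, and two-patch acquisition diffusions drawn from the
multiplicative social-transmission model — so parameter recovery and
every downstream stage can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import (
    BIRD,
    FLOCK,
    LOCATION,
    TIME,
    FollowingNetworkSet,
    build_following_networks,
    count_total_visits,
    detect_following_events,
    transmission_weights,
)
from .oada import Diffusion, DiffusionSet, encode_covariates
from .scenario import SyntheticScenario

__all__ = [
    "generate_roster",
    "generate_pretraining_log",
    "simulate_diffusions",
    "generate_dataset",
    "PretrainingTruth",
    "SyntheticDataset",
]

#: minimum spacing between accepted initiation events; keeps every planted
#: arrival cluster (initiator, followers within 5 s, independent arrivals
#: 5-30 s later) unambiguous under the 5-s windowing rule
_MIN_CLUSTER_GAP_S = 40.0


@dataclass
class PretrainingTruth:
    """Ground truth planted by the pre-training generator."""

    follow_events: pd.DataFrame  # flock_id, initiator, follower, timestamp_s
    visit_counts: dict[str, int]


@dataclass
class SyntheticDataset:
    """Full synthetic bundle: roster with activity/weights, arrival log,
    planted truth, following + homogeneous networks, diffusions."""

    scenario: SyntheticScenario
    roster: pd.DataFrame
    arrivals: pd.DataFrame
    truth: PretrainingTruth
    networks: dict[str, FollowingNetworkSet]
    diffusions: DiffusionSet
    exposures_at_acquisition: dict = field(default_factory=dict)


def _flock_ids(n: int) -> list[str]:
    return [f"F{k + 1:02d}" for k in range(n)]


def generate_roster(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Roster of birds: balanced sexes, ages in years, informed flags.

    With two informed birds per flock, one male and one female are
    trained, mirroring the study design; otherwise informed birds are
    spread across sexes as evenly as possible.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    rows = []
    for flock in _flock_ids(scenario.n_flocks):
        n = scenario.flock_size
        sexes = np.array(["M", "F"])[np.arange(n) % 2]
        ages = np.round(rng.uniform(1.0, 6.0, size=n), 1)
        informed = np.zeros(n, dtype=bool)
        order = []  # alternate sexes when picking who gets trained
        males = list(rng.permutation(np.flatnonzero(sexes == "M")))
        females = list(rng.permutation(np.flatnonzero(sexes == "F")))
        while males or females:
            if males:
                order.append(males.pop())
            if females:
                order.append(females.pop())
        informed[order[: scenario.n_informed_per_flock]] = True
        for k in range(n):
            rows.append(
                (f"{flock}_B{k + 1:02d}", flock, sexes[k], ages[k], bool(informed[k]))
            )
    roster = pd.DataFrame(rows, columns=[BIRD, FLOCK, "sex", "age", "informed"])
    return roster


def generate_pretraining_log(
    roster: pd.DataFrame,
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, PretrainingTruth]:
    """Simulate feeder arrivals over the pre-training period.

    Each bird initiates visits as a Poisson process with a
    Gamma-heterogeneous rate (skewed sociability); at each initiation
    every other bird follows within (0, 5) s with its own probability,
    or arrives independently 5-30 s later (a non-following), and
    occasionally a second bird arrives at the identical timestamp (a
    group arrival, which has no initiator).  Arrival clusters are spaced
    so the 5-s windowing rule recovers the planted follower pairs
    exactly; planted events and visit counts are returned as ground
    truth.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    duration_s = scenario.pretrain_duration_h * 3600.0
    arrivals: list[tuple[str, str, float, str]] = []
    planted: list[tuple[str, str, str, float]] = []

    for flock, grp in roster.groupby(FLOCK, sort=True):
        birds = sorted(grp[BIRD])
        n = len(birds)
        soc = rng.gamma(scenario.sociability_shape, scenario.sociability_scale, size=n)
        init_rate = scenario.mean_initiation_rate_per_h * soc / max(soc.mean(), 1e-12)
        # pairwise preferences: who tends to follow whom; Gamma with shape < 1
        # concentrates each bird's following on a few flock-mates, giving the
        # skewed strength distributions characteristic of real flocks
        k_pref = scenario.pair_preference_shape
        pref = rng.gamma(k_pref, 1.0 / k_pref, size=(n, n))
        np.fill_diagonal(pref, 0.0)
        follow_p = np.minimum(
            0.95,
            scenario.follow_prob
            * (soc / max(soc.mean(), 1e-12))[:, None]
            * pref,
        )  # follow_p[k, j] = P(bird k follows initiator j)
        total_rate_s = init_rate.sum() / 3600.0
        # merged initiation process, thinned to keep clusters separated
        t, last_cluster = 0.0, -np.inf
        while True:
            t += rng.exponential(1.0 / total_rate_s)
            if t > duration_s:
                break
            if t - last_cluster < _MIN_CLUSTER_GAP_S:
                continue
            last_cluster = t
            j = int(rng.choice(n, p=init_rate / init_rate.sum()))
            initiator = birds[j]
            if rng.random() < scenario.group_arrival_prob and n > 1:
                # group arrival: a second bird at the identical timestamp,
                # no initiator, no followers planted
                other = int(rng.choice([k for k in range(n) if k != j]))
                arrivals.append((flock, initiator, t, "central_feeder"))
                arrivals.append((flock, birds[other], t, "central_feeder"))
                continue
            arrivals.append((flock, initiator, t, "central_feeder"))
            cluster_last = t
            nonfollowers = []
            for k in range(n):
                if k == j:
                    continue
                if rng.random() < follow_p[k, j]:
                    offset = rng.uniform(0.3, 4.7)
                    arrivals.append((flock, birds[k], t + offset, "central_feeder"))
                    planted.append((flock, initiator, birds[k], t + offset))
                    cluster_last = max(cluster_last, t + offset)
                elif rng.random() < scenario.nonfollow_prob:
                    nonfollowers.append(k)
            # independent late arrivals, each opening (and closing) its own
            # empty window: > 5 s after everything earlier in the cluster
            for k in nonfollowers:
                t_k = cluster_last + 5.5 + rng.uniform(0.0, 3.0)
                if t_k - t > 30.0:
                    break
                arrivals.append((flock, birds[k], t_k, "central_feeder"))
                cluster_last = t_k

    log = (
        pd.DataFrame(arrivals, columns=[FLOCK, BIRD, TIME, LOCATION])
        .sort_values([FLOCK, TIME, BIRD], kind="mergesort")
        .reset_index(drop=True)
    )
    truth = PretrainingTruth(
        follow_events=pd.DataFrame(
            planted, columns=[FLOCK, "initiator", "follower", TIME]
        )
        .sort_values([FLOCK, TIME], kind="mergesort")
        .reset_index(drop=True),
        visit_counts=count_total_visits(log, birds=list(roster[BIRD])),
    )
    return log, truth


def simulate_diffusions(
    roster: pd.DataFrame,
    networks: FollowingNetworkSet,
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
    collect_exposures: bool = False,
) -> DiffusionSet | tuple[DiffusionSet, dict]:
    """Sequentially simulate the two-patch acquisition diffusions.

    Per flock and patch, each naive bird i acquires with hazard
    lambda_i = lambda0_patch * exp(beta.x_i + u_flock + v_i) * (1 + s_patch * T_i),
    T_i = sum_j a(i,j) w_j z_j; waiting times are exponential in the total
    hazard and the acquirer is drawn categorically, until the censoring
    horizon.  Informed birds are demonstrators for both patches from t=0
    and never acquire; birds never acquiring are censored at exactly the
    horizon.  Patch labels carry the generator's ground truth: patch 1 is
    the patch with s_true[0] and baseline_rates[0].
    """
    rng = np.random.default_rng(scenario.seed + 2) if rng is None else rng
    if "transmission_weight" not in roster.columns:
        roster = roster.assign(transmission_weight=1.0)
    covs = sorted(scenario.beta_true)
    X, _ = encode_covariates(roster, covs)
    beta = np.array([scenario.beta_true[c] for c in covs])
    eta_fixed = X @ beta if covs else np.zeros(len(roster))
    eta_by_bird = dict(zip(roster[BIRD], eta_fixed))
    w_by_bird = dict(zip(roster[BIRD], roster["transmission_weight"].astype(float)))

    flocks = sorted(roster[FLOCK].unique())
    u = rng.normal(0.0, np.sqrt(scenario.sigma_flock2), size=len(flocks))
    u_by_flock = dict(zip(flocks, u))
    v_by_bird = dict(
        zip(roster[BIRD], rng.normal(0.0, np.sqrt(scenario.sigma_ind2), size=len(roster)))
    )

    out: DiffusionSet = []
    exposures: dict[tuple[str, int, str], float] = {}
    for flock in flocks:
        grp = roster[roster[FLOCK] == flock]
        net = networks[flock]
        nodes = net.nodes
        idx = {b: k for k, b in enumerate(nodes)}
        informed = set(grp.loc[grp["informed"].astype(bool), BIRD])
        naive0 = [b for b in nodes if b not in informed]
        w = np.array([w_by_bird[b] for b in nodes])
        Aw = net.adjacency * w[None, :]
        eta = np.array(
            [eta_by_bird[b] + u_by_flock[flock] + v_by_bird[b] for b in nodes]
        )
        for patch in (1, 2):
            lam0 = scenario.baseline_rates[patch - 1]
            s = scenario.s_true[patch - 1]
            z = np.array([1.0 if b in informed else 0.0 for b in nodes])
            alive = np.array([b not in informed for b in nodes])
            t = 0.0
            acq: list[tuple[str, float]] = []
            while alive.any():
                T = Aw @ z
                lam = lam0 * np.exp(eta) * (1.0 + s * T) * alive
                total = lam.sum()
                if not np.isfinite(total) or total <= 0:
                    raise FloatingPointError("nonfinite total hazard in simulation")
                t += rng.exponential(1.0 / total)
                if t > scenario.censor_time_s:
                    break
                k = int(rng.choice(len(nodes), p=lam / total))
                acq.append((nodes[k], t))
                if collect_exposures:
                    exposures[(flock, patch, nodes[k])] = float(T[k])
                alive[k] = False
                z[k] = 1.0
            censored = frozenset(b for b in naive0 if b not in {a for a, _ in acq})
            out.append(
                Diffusion(
                    flock=flock,
                    patch_rank=patch,
                    acquisitions=acq,
                    censored=censored,
                    demonstrators=frozenset(informed),
                )
            )
    if collect_exposures:
        return out, exposures
    return out


def generate_dataset(
    scenario: SyntheticScenario, seed: int | None = None
) -> SyntheticDataset:
    """End-to-end synthetic bundle: roster -> pre-training log ->
    networks (following + homogeneous) -> transmission weights ->
    simulated diffusions."""
    from .networks import homogeneous_networks

    master = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    r_roster, r_log, r_diff = [np.random.default_rng(s) for s in ss.spawn(3)]

    roster = generate_roster(scenario, rng=r_roster)
    log, truth = generate_pretraining_log(roster, scenario, rng=r_log)
    roster = roster.assign(
        feeding_activity=[truth.visit_counts[b] for b in roster[BIRD]]
    )
    weights = transmission_weights(
        truth.visit_counts, dict(zip(roster[BIRD], roster[FLOCK]))
    )
    roster = roster.assign(transmission_weight=[weights[b] for b in roster[BIRD]])

    events = detect_following_events(log)
    networks = {
        "following": build_following_networks(
            events, scenario.pretrain_duration_h, roster
        ),
        "homogeneous": homogeneous_networks(roster),
    }
    diffusions, exposures = simulate_diffusions(
        roster, networks["following"], scenario, rng=r_diff, collect_exposures=True
    )
    return SyntheticDataset(
        scenario=scenario,
        roster=roster,
        arrivals=log,
        truth=truth,
        networks=networks,
        diffusions=diffusions,
        exposures_at_acquisition=exposures,
    )
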