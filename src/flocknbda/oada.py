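"""Order-of-acquisition diffusion analysis (OADA) with stratified
multi-diffusion partial likelihood.

The model: each naive bird i acquires the trait (first feeding at a
hidden food patch) with hazard

    lambda_i(t) = lambda0_patch(t) * exp(beta.x_i + u_flock + v_i) * (1 + s_patch * T_i(t))

where T_i = sum_j a(i,j) * w_j * z_j(t) is the network-weighted exposure
to informed birds (a = following rate of i toward j, w = transmission
weight, z = informed status), s_patch is the social-transmission
parameter of the patch stratum, beta are covariate effects, and u, v are
flock- and individual-level random effects ("individual nested in
flock").  Fitting uses the Cox-type partial likelihood on the order of
acquisition only, so the baseline lambda0 cancels and its shape is
irrelevant.  Diffusions are combined into one dataset and stratified by
patch rank (or flock x patch), each stratum carrying its own baseline.

Random effects are integrated out by a Laplace approximation to the
marginal partial likelihood (a penalized-partial-likelihood inner Newton
step, as in mixed-effect proportional-hazards fitting); with variances
fixed at zero this reduces exactly to the fixed-effects OADA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .networks import BIRD, FLOCK, FollowingNetwork, FollowingNetworkSet

__all__ = [
    "Diffusion",
    "DiffusionSet",
    "ModelSpec",
    "FitResult",
    "OadaData",
    "SCENARIOS",
    "assign_patch_strata",
    "social_exposure",
    "next_acquirer_probabilities",
    "build_oada_data",
    "oada_negloglik",
    "fit_oada",
    "profile_ci",
    "lrt_vs_asocial",
    "encode_covariates",
]

#: scenario name -> number of free social-transmission parameters
SCENARIOS = {
    "asocial": 0,
    "shared_s": 1,
    "separate_s": 2,
    "s_patch1_only": 1,
    "s_patch2_only": 1,
}

COVARIATES = ("age", "sex", "feeding_activity")

S_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# data containers


@dataclass
class Diffusion:
    """One acquisition diffusion: a flock at one patch stratum.

    ``acquisitions`` is the observed order (bird, latency_s) of first
    feedings among naive birds; ``censored`` birds never fed before the
    horizon; ``demonstrators`` are the informed birds, in state 1 from
    t=0 and never acquirers.
    """

    flock: str
    patch_rank: int
    acquisitions: list[tuple[str, float]]
    censored: frozenset[str]
    demonstrators: frozenset[str]

    def __post_init__(self) -> None:
        self.censored = frozenset(self.censored)
        self.demonstrators = frozenset(self.demonstrators)
        lat = [t for _, t in self.acquisitions]
        if any(b - a <= 0 for a, b in zip(lat, lat[1:])):
            raise ValueError(
                f"latencies must be strictly increasing in diffusion "
                f"({self.flock}, patch {self.patch_rank})"
            )
        acq = {b for b, _ in self.acquisitions}
        if acq & self.demonstrators:
            raise ValueError("demonstrators cannot appear as acquirers")
        if acq & self.censored:
            raise ValueError("acquirers cannot be censored")

    @property
    def naive(self) -> frozenset[str]:
        return frozenset(b for b, _ in self.acquisitions) | self.censored

    @property
    def birds(self) -> frozenset[str]:
        return self.naive | self.demonstrators


DiffusionSet = list


def diffusions_to_frame(diffusions: DiffusionSet, censor_time_s: float) -> pd.DataFrame:
    rows = []
    for d in diffusions:
        for b, t in d.acquisitions:
            rows.append((d.flock, d.patch_rank, b, t, False))
        for b in sorted(d.censored):
            rows.append((d.flock, d.patch_rank, b, censor_time_s, True))
    return pd.DataFrame(
        rows, columns=[FLOCK, "patch_rank", BIRD, "latency_s", "censored"]
    )


def diffusions_from_frame(df: pd.DataFrame, roster: pd.DataFrame) -> DiffusionSet:
    """Rebuild a DiffusionSet from the diffusion CSV layout, with
    demonstrators taken from the roster's ``informed`` column."""
    informed = {
        f: frozenset(g.loc[g["informed"].astype(bool), BIRD])
        for f, g in roster.groupby(FLOCK)
    }
    out: DiffusionSet = []
    for (flock, rank), grp in df.groupby([FLOCK, "patch_rank"], sort=True):
        obs = grp[~grp["censored"].astype(bool)].sort_values("latency_s")
        acq = list(zip(obs[BIRD], obs["latency_s"].astype(float)))
        cen = frozenset(grp.loc[grp["censored"].astype(bool), BIRD])
        out.append(
            Diffusion(
                flock=str(flock),
                patch_rank=int(rank),
                acquisitions=acq,
                censored=cen,
                demonstrators=informed.get(flock, frozenset()),
            )
        )
    return out


def assign_patch_strata(
    latencies: pd.DataFrame,
    roster: pd.DataFrame,
    censor_time_s: float,
    tie_break: str | None = None,
) -> DiffusionSet:
    """Rank each flock's physical patches by discovery order.

    ``latencies`` has columns flock_id, patch_id, bird_id, latency_s,
    censored.  Within a flock, the patch with the earlier first feeding
    (minimum uncensored latency) gets patch_rank 1 and the other rank 2.
    A patch never fed from is rank 2 by convention and yields a diffusion
    with zero acquisitions and all-naive censoring.  Equal first
    latencies raise unless ``tie_break='patch_id'``.
    """
    informed = {
        f: frozenset(g.loc[g["informed"].astype(bool), BIRD])
        for f, g in roster.groupby(FLOCK)
    }
    naive_by_flock = {
        f: set(g.loc[~g["informed"].astype(bool), BIRD])
        for f, g in roster.groupby(FLOCK)
    }
    out: DiffusionSet = []
    for flock, fgrp in latencies.groupby(FLOCK, sort=True):
        patches = sorted(fgrp["patch_id"].unique())
        if len(patches) > 2:
            raise ValueError(f"flock {flock} has more than two patches")
        firsts = {}
        for p in patches:
            obs = fgrp[(fgrp["patch_id"] == p) & (~fgrp["censored"].astype(bool))]
            firsts[p] = obs["latency_s"].min() if len(obs) else np.inf
        order = sorted(patches, key=lambda p: (firsts[p], str(p)))
        vals = [firsts[p] for p in patches]
        if len(patches) == 2 and vals[0] == vals[1] and np.isfinite(vals[0]):
            if tie_break != "patch_id":
                raise ValueError(
                    f"flock {flock}: tied first-feeding latencies; "
                    "set tie_break='patch_id' to break by patch label"
                )
        for rank, p in enumerate(order, start=1):
            pgrp = fgrp[fgrp["patch_id"] == p]
            obs = pgrp[~pgrp["censored"].astype(bool)].sort_values("latency_s")
            acq = list(zip(obs[BIRD], obs["latency_s"].astype(float)))
            # every naive bird not observed feeding carries the horizon
            cen = naive_by_flock.get(flock, set()) - {b for b, _ in acq}
            out.append(
                Diffusion(
                    flock=str(flock),
                    patch_rank=rank,
                    acquisitions=acq,
                    censored=frozenset(cen),
                    demonstrators=informed.get(flock, frozenset()),
                )
            )
    return out


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ModelSpec:
    """One OADA model: network type, social-transmission scenario,
    covariate set, random-effect structure, and pooling rule."""

    network_type: str | None = "following"  # following | homogeneous | None (asocial)
    scenario: str = "separate_s"
    covariates: tuple[str, ...] = ()
    random_effects: str = "none"  # none | flock | flock_plus_individual
    pooling: str = "pool_flocks_within_patch"  # or stratify_flock_by_patch

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.random_effects not in ("none", "flock", "flock_plus_individual"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.pooling not in ("pool_flocks_within_patch", "stratify_flock_by_patch"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.scenario != "asocial" and self.network_type is None:
            raise ValueError("social scenarios need a network_type")
        unknown = set(self.covariates) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates {sorted(unknown)}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def n_s(self) -> int:
        return SCENARIOS[self.scenario]

    @property
    def n_variance(self) -> int:
        return {"none": 0, "flock": 1, "flock_plus_individual": 2}[self.random_effects]

    def s_multipliers(self, patch_rank: int) -> np.ndarray:
        """Row of the map s_patch = M @ s_free for this patch rank."""
        m = np.zeros(self.n_s)
        if self.scenario == "shared_s":
            m[0] = 1.0
        elif self.scenario == "separate_s":
            m[patch_rank - 1] = 1.0
        elif self.scenario == "s_patch1_only" and patch_rank == 1:
            m[0] = 1.0
        elif self.scenario == "s_patch2_only" and patch_rank == 2:
            m[0] = 1.0
        return m

    def param_names(self) -> list[str]:
        s_names = {
            "asocial": [],
            "shared_s": ["s"],
            "separate_s": ["s1", "s2"],
            "s_patch1_only": ["s1"],
            "s_patch2_only": ["s2"],
        }[self.scenario]
        v_names = {
            "none": [],
            "flock": ["log_sigma2_flock"],
            "flock_plus_individual": ["log_sigma2_flock", "log_sigma2_ind"],
        }[self.random_effects]
        return s_names + [f"beta:{c}" for c in self.covariates] + v_names


@dataclass
class FitResult:
    """Maximum (marginal) partial-likelihood fit of one ModelSpec."""

    spec: ModelSpec
    s_hat: dict[int, float]  # patch_rank -> estimate
    s_boundary: dict[int, bool]  # True where constrained to 0
    beta_hat: dict[str, float]
    variance_hat: dict[str, float]
    loglik: float
    n_events: int
    k_params: int
    aicc: float
    converged: bool
    params: np.ndarray = field(default_factory=lambda: np.empty(0))
    profile_cis: dict[str, tuple[float, float]] = field(default_factory=dict)

    def summary(self) -> str:
        bits = [f"logL={self.loglik:.3f}", f"AICc={self.aicc:.2f}"]
        for p, v in self.s_hat.items():
            flag = " (constrained to 0)" if self.s_boundary.get(p) else ""
            bits.append(f"s{p}={v:.4g}{flag}")
        bits += [f"beta[{c}]={v:.4g}" for c, v in self.beta_hat.items()]
        bits += [f"{k}={v:.4g}" for k, v in self.variance_hat.items()]
        return ", ".join(bits)


# ---------------------------------------------------------------------------
# covariate encoding (shared with the synthetic generator)


def encode_covariates(
    roster: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the asocial rate: sex as male=1/female=0, age in
    years as-is, feeding activity z-scored across the roster (shifts
    cancel in the partial likelihood; the z-scale keeps beta O(1))."""
    cols = []
    for c in covariates:
        if c == "sex":
            cols.append((roster["sex"].astype(str) == "M").to_numpy(dtype=float))
        elif c == "age":
            cols.append(roster["age"].to_numpy(dtype=float))
        elif c == "feeding_activity":
            v = roster["feeding_activity"].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            cols.append((v - v.mean()) / sd if sd > 0 else np.zeros_like(v))
        else:
            raise ValueError(f"unknown covariate {c!r}")
    X = np.column_stack(cols) if cols else np.zeros((len(roster), 0))
    return X, list(covariates)


# ---------------------------------------------------------------------------
# elementary model pieces


def social_exposure(
    net: FollowingNetwork,
    status: Mapping[str, int],
    weights: Mapping[str, float],
    bird: str,
) -> float:
    """Network-weighted exposure T_i = sum_j a(i,j) w_j z_j of a naive bird."""
    return float(
        sum(
            net.weight(bird, j) * float(weights.get(j, 1.0)) * int(status.get(j, 0))
            for j in net.nodes
            if j != bird
        )
    )


def next_acquirer_probabilities(
    risk_set: Sequence[str],
    s: float,
    exposures: Mapping[str, float],
    log_rate: Mapping[str, float] | None = None,
) -> np.ndarray:
    """p_i = lambda_i / sum lambda over the risk set, with
    lambda_i = exp(log_rate_i) * (1 + s * T_i); the baseline cancels."""
    if not len(risk_set):
        raise ValueError("risk set is empty")
    if s < 0:
        raise ValueError("s must be nonnegative")
    eta = np.array([0.0 if log_rate is None else log_rate.get(b, 0.0) for b in risk_set])
    T = np.array([exposures.get(b, 0.0) for b in risk_set])
    lam = np.exp(eta) * (1.0 + s * T)
    tot = lam.sum()
    if not np.isfinite(tot) or tot <= 0:
        raise FloatingPointError("all hazards vanish or are nonfinite")
    return lam / tot


# ---------------------------------------------------------------------------
# likelihood data preparation


@dataclass
class _Stratum:
    key: object
    patch_rank: int
    acq_idx: np.ndarray  # (E,) global bird index of each acquirer
    risk: np.ndarray  # (E, N) bool risk-set membership
    T: dict[str, np.ndarray]  # network_type -> (E, N) exposures


@dataclass
class OadaData:
    """Precomputed event-level arrays for fast likelihood evaluation.

    Exposures depend only on the data, networks and weights — never on
    the parameters — so they are computed once per dataset.
    """

    birds: list[str]
    flock_of: list[str]
    roster: pd.DataFrame
    strata: list[_Stratum]
    n_events: int
    pooling: str
    orientation: str
    network_types: tuple[str, ...]

    def X(self, covariates: Sequence[str]) -> np.ndarray:
        X, _ = encode_covariates(self.roster, covariates)
        return X

    def random_effect_design(self, random_effects: str) -> tuple[np.ndarray, list[int]]:
        """Z (N x q) and the block sizes of (flock, individual) effects."""
        n = len(self.birds)
        flocks = sorted(set(self.flock_of))
        fidx = {f: k for k, f in enumerate(flocks)}
        Zf = np.zeros((n, len(flocks)))
        for i, f in enumerate(self.flock_of):
            Zf[i, fidx[f]] = 1.0
        if random_effects == "flock":
            return Zf, [len(flocks)]
        if random_effects == "flock_plus_individual":
            return np.hstack([Zf, np.eye(n)]), [len(flocks), n]
        return np.zeros((n, 0)), []


def build_oada_data(
    diffusions: DiffusionSet,
    networks: Mapping[str, FollowingNetworkSet],
    roster: pd.DataFrame,
    pooling: str = "pool_flocks_within_patch",
    orientation: str = "follower_to_followed",
) -> OadaData:
    """Replay the merged event order once and tabulate risk sets and
    exposures per stratum and per network type.

    ``networks`` maps network type ("following", "homogeneous", ...) to a
    per-flock FollowingNetworkSet.  Under flock pooling, events of all
    flocks in a patch stratum are merged in latency order (ties broken by
    flock then bird id) and risk sets span every still-naive bird of the
    stratum; informed status still propagates only within a flock because
    networks carry no cross-flock edges.
    """
    if orientation not in ("follower_to_followed", "transpose"):
        raise ValueError(f"unknown orientation {orientation!r}")
    roster = roster.sort_values([FLOCK, BIRD], kind="mergesort").reset_index(drop=True)
    birds = list(roster[BIRD])
    flock_of = list(roster[FLOCK].astype(str))
    index = {b: k for k, b in enumerate(birds)}
    n = len(birds)

    weights = (
        roster["transmission_weight"].to_numpy(dtype=float)
        if "transmission_weight" in roster
        else np.ones(n)
    )

    # global block-diagonal weighted adjacency per network type
    Aw: dict[str, np.ndarray] = {}
    for ntype, nets in networks.items():
        A = np.zeros((n, n))
        for fl, net in nets.items():
            gl = [index[b] for b in net.nodes]
            adj = net.adjacency if orientation == "follower_to_followed" else net.adjacency.T
            A[np.ix_(gl, gl)] = adj
        Aw[ntype] = A * weights[None, :]

    def stratum_key(d: Diffusion):
        if pooling == "pool_flocks_within_patch":
            return d.patch_rank
        return (d.flock, d.patch_rank)

    groups: dict[object, list[Diffusion]] = {}
    for d in diffusions:
        groups.setdefault(stratum_key(d), []).append(d)

    strata: list[_Stratum] = []
    n_events = 0
    for key in sorted(groups, key=str):
        dgroup = groups[key]
        patch_rank = dgroup[0].patch_rank
        events = sorted(
            (t, d.flock, b) for d in dgroup for b, t in d.acquisitions
        )  # latency, then flock id, then bird id breaks cross-flock ties
        naive = sorted(
            {b for d in dgroup for b in d.naive}, key=lambda b: index[b]
        )
        z = np.zeros(n)
        for d in dgroup:
            for b in d.demonstrators:
                z[index[b]] = 1.0
        alive = np.zeros(n, dtype=bool)
        for b in naive:
            alive[index[b]] = True
        E = len(events)
        acq_idx = np.zeros(E, dtype=int)
        risk = np.zeros((E, n), dtype=bool)
        T = {ntype: np.zeros((E, n)) for ntype in Aw}
        for e, (_t, _fl, b) in enumerate(events):
            bi = index[b]
            risk[e] = alive
            for ntype, A in Aw.items():
                T[ntype][e] = A @ z
            acq_idx[e] = bi
            alive[bi] = False
            z[bi] = 1.0
        strata.append(_Stratum(key=key, patch_rank=patch_rank, acq_idx=acq_idx, risk=risk, T=T))
        n_events += E
    return OadaData(
        birds=birds,
        flock_of=flock_of,
        roster=roster,
        strata=strata,
        n_events=n_events,
        pooling=pooling,
        orientation=orientation,
        network_types=tuple(Aw),
    )


# ---------------------------------------------------------------------------
# partial likelihood


def _partial_loglik_terms(
    data: OadaData,
    spec: ModelSpec,
    s_free: np.ndarray,
    eta: np.ndarray,
    want_grad: bool = False,
    X: np.ndarray | None = None,
):
    """Sum of log next-acquirer probabilities; optionally d/d(s, beta)
    and the per-bird score dl/d(eta_i) needed for random effects."""
    n_s = spec.n_s
    ntype = spec.network_type if n_s else None
    exp_eta = np.exp(eta)
    ll = 0.0
    g_s = np.zeros(n_s)
    g_beta = np.zeros(X.shape[1]) if (want_grad and X is not None) else None
    score_eta = np.zeros(len(eta)) if want_grad else None
    pis: list[tuple[np.ndarray, np.ndarray]] = []  # (stratum, pi) per stratum, for frailty Hessian
    for st in data.strata:
        mult = spec.s_multipliers(st.patch_rank)  # (n_s,)
        s_patch = float(mult @ s_free) if n_s else 0.0
        T = st.T[ntype] if ntype is not None else 0.0
        soc = 1.0 + s_patch * T  # (E, N), or scalar 1 when asocial
        lam = exp_eta[None, :] * soc * st.risk
        denom = lam.sum(axis=1)
        E = len(st.acq_idx)
        rows = np.arange(E)
        num = lam[rows, st.acq_idx]
        if np.any(num <= 0) or np.any(~np.isfinite(denom)) or np.any(denom <= 0):
            raise FloatingPointError(
                f"nonfinite or zero hazard in stratum {st.key!r}"
            )
        ll += float(np.log(num).sum() - np.log(denom).sum())
        if want_grad:
            pi = lam / denom[:, None]  # (E, N)
            pis.append((st, pi))
            if n_s:
                dlog = T / soc  # d log(1+sT)/ds_patch
                contrib = dlog[rows, st.acq_idx] - (pi * dlog).sum(axis=1)
                g_s += mult * contrib.sum()
            if g_beta is not None and X.shape[1]:
                xa = X[st.acq_idx]  # (E, p)
                g_beta += (xa - pi @ X).sum(axis=0)
            if score_eta is not None:
                np.add.at(score_eta, st.acq_idx, 1.0)
                score_eta -= pi.sum(axis=0)
    return ll, g_s, g_beta, score_eta, pis


def oada_negloglik(
    params: np.ndarray,
    spec: ModelSpec,
    data: OadaData | DiffusionSet,
    networks: Mapping[str, FollowingNetworkSet] | None = None,
    roster: pd.DataFrame | None = None,
) -> float:
    """Negative stratified partial log-likelihood at fixed parameters.

    ``params`` stacks [s_free..., beta...] in ModelSpec order (variance
    components, if any, are not part of this fixed-effects evaluation).
    Accepts either a prebuilt :class:`OadaData` or raw diffusions plus
    networks and roster.
    """
    if not isinstance(data, OadaData):
        data = build_oada_data(
            data, networks, roster, pooling=spec.pooling
        )
    params = np.asarray(params, dtype=float)
    n_s = spec.n_s
    s_free = params[:n_s]
    if (s_free < 0).any():
        raise ValueError("s parameters must be nonnegative")
    X = data.X(spec.covariates)
    beta = params[n_s : n_s + X.shape[1]]
    eta = X @ beta
    ll, *_ = _partial_loglik_terms(data, spec, s_free, eta)
    return -ll


def _fixed_nll_and_grad(theta, spec, data, X):
    n_s = spec.n_s
    s_free = np.maximum(theta[:n_s], 0.0)
    beta = theta[n_s:]
    eta = X @ beta
    ll, g_s, g_beta, _, _ = _partial_loglik_terms(
        data, spec, s_free, eta, want_grad=True, X=X
    )
    g = np.concatenate([g_s, g_beta if g_beta is not None else np.empty(0)])
    return -ll, -g


# --- Laplace-approximated marginal likelihood for random effects ----------


def _laplace_marginal_nll(theta, spec, data, X, Z, blocks):
    """-log marginal partial likelihood, random effects integrated out by
    Laplace approximation with an inner Newton solve for the modes."""
    n_s = spec.n_s
    p = X.shape[1]
    s_free = np.maximum(theta[:n_s], 0.0)
    beta = theta[n_s : n_s + p]
    log_var = theta[n_s + p :]
    variances = np.exp(log_var)
    q = Z.shape[1]
    prec_diag = np.concatenate(
        [np.full(sz, 1.0 / v) for sz, v in zip(blocks, variances)]
    )
    b = np.zeros(q)
    eta_fix = X @ beta

    def inner(b):
        eta = eta_fix + Z @ b
        ll, _, _, score_eta, pis = _partial_loglik_terms(
            data, spec, s_free, eta, want_grad=True, X=None
        )
        pen = 0.5 * float(b @ (prec_diag * b))
        grad = Z.T @ score_eta - prec_diag * b
        return ll - pen, grad, pis

    f, grad, pis = inner(b)
    for _ in range(60):
        if np.max(np.abs(grad)) < 1e-9:
            break
        # information matrix A = sum_e diag(pi) - pi pi'
        n = Z.shape[0]
        Adiag = np.zeros(n)
        P_list = []
        for st, pi in pis:
            Adiag += pi.sum(axis=0)
            P_list.append(pi)
        P = np.vstack(P_list)
        W = np.diag(Adiag) - P.T @ P
        H = Z.T @ W @ Z + np.diag(prec_diag)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.maximum(np.diag(H), 1e-8)
        t = 1.0
        for _ls in range(30):
            f_new, grad_new, pis_new = inner(b + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        b = b + t * step
        f, grad, pis = f_new, grad_new, pis_new
    # Laplace correction at the mode
    n = Z.shape[0]
    Adiag = np.zeros(n)
    P_list = []
    for st, pi in pis:
        Adiag += pi.sum(axis=0)
        P_list.append(pi)
    P = np.vstack(P_list)
    W = np.diag(Adiag) - P.T @ P
    H = Z.T @ W @ Z + np.diag(prec_diag)
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf
    logdet_Sigma = -float(np.log(prec_diag).sum())
    return -(f - 0.5 * logdet_Sigma - 0.5 * logdet_H)


def marginal_negloglik(theta, spec, data: OadaData) -> float:
    """Negative (marginal) partial log-likelihood including any random
    effects; with ``random_effects='none'`` equals :func:`oada_negloglik`."""
    X = data.X(spec.covariates)
    if spec.random_effects == "none":
        return _fixed_nll_and_grad(
            np.asarray(theta, dtype=float), spec, data, X
        )[0]
    Z, blocks = data.random_effect_design(spec.random_effects)
    return _laplace_marginal_nll(np.asarray(theta, dtype=float), spec, data, X, Z, blocks)


# ---------------------------------------------------------------------------
# fitting


_MULTISTART_S = (0.1, 1.0, 5.0)
S_UPPER = 1e4


def _bounds(spec: ModelSpec, p: int):
    return (
        [(0.0, S_UPPER)] * spec.n_s
        + [(-50.0, 50.0)] * p
        + [(-12.0, 6.0)] * spec.n_variance
    )


def fit_oada(
    spec: ModelSpec,
    diffusions: DiffusionSet | OadaData,
    networks: Mapping[str, FollowingNetworkSet] | None = None,
    roster: pd.DataFrame | None = None,
    aicc_n: int | None = None,
) -> FitResult:
    """Maximize the (marginal) stratified partial likelihood.

    s parameters are box-constrained at 0 (deterministic three-point
    multistart guards against local optima); an estimate on the boundary
    is flagged "constrained to 0".  AICc uses k = free s + |beta| +
    variance components and n = total acquisition events unless
    ``aicc_n`` overrides it.
    """
    data = (
        diffusions
        if isinstance(diffusions, OadaData)
        else build_oada_data(diffusions, networks, roster, pooling=spec.pooling)
    )
    if data.n_events < 1:
        raise ValueError("no acquisition events to fit")
    X = data.X(spec.covariates)
    p = X.shape[1]
    n_s = spec.n_s
    bounds = _bounds(spec, p)

    if not bounds:  # zero-parameter model: the likelihood is a constant
        nll = _fixed_nll_and_grad(np.empty(0), spec, data, X)[0]
        best = optimize.OptimizeResult(x=np.empty(0), fun=nll, success=True)
        starts = ()
    else:
        best = None
        starts = _MULTISTART_S if n_s else (0.0,)
    for s0 in starts:
        theta0 = np.concatenate(
            [np.full(n_s, s0), np.zeros(p), np.full(spec.n_variance, np.log(0.5))]
        )
        if spec.random_effects == "none":
            res = optimize.minimize(
                _fixed_nll_and_grad,
                theta0,
                args=(spec, data, X),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
        else:
            res = optimize.minimize(
                marginal_negloglik,
                theta0,
                args=(spec, data),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-11, "gtol": 1e-8, "maxiter": 300},
            )
        if best is None or (res.fun < best.fun - 1e-12):
            best = res

    theta = np.asarray(best.x, dtype=float)
    converged = bool(best.success) and np.isfinite(best.fun)
    if not converged and np.isfinite(best.fun) and bounds:
        # a line-search abort at an already-stationary point is still a
        # converged fit: accept when the projected gradient vanishes
        if spec.random_effects == "none":
            _, g = _fixed_nll_and_grad(theta, spec, data, X)
        else:
            g = optimize.approx_fprime(
                theta, marginal_negloglik, 1e-6, spec, data
            )
        proj = g.copy()
        for i, (lo, hi) in enumerate(bounds):
            if (theta[i] <= lo + 1e-12 and g[i] > 0) or (
                theta[i] >= hi - 1e-12 and g[i] < 0
            ):
                proj[i] = 0.0
        converged = bool(np.max(np.abs(proj)) < 1e-3)
    loglik = -float(best.fun)
    s_free = theta[:n_s]
    beta = theta[n_s : n_s + p]
    log_var = theta[n_s + p :]

    s_hat: dict[int, float] = {}
    s_boundary: dict[int, bool] = {}
    for rank in (1, 2):
        mult = spec.s_multipliers(rank)
        val = float(mult @ s_free) if n_s else 0.0
        s_hat[rank] = val
        s_boundary[rank] = bool(mult.any()) and val < S_BOUNDARY_TOL
    variance_names = {
        "none": [],
        "flock": ["sigma2_flock"],
        "flock_plus_individual": ["sigma2_flock", "sigma2_ind"],
    }[spec.random_effects]
    k = n_s + p + spec.n_variance
    n = aicc_n if aicc_n is not None else data.n_events
    from .selection import aicc as _aicc  # local import avoids cycle

    try:
        aicc_val = _aicc(loglik, k, n)
    except ValueError:
        aicc_val = np.inf
        converged = False
    return FitResult(
        spec=spec,
        s_hat=s_hat,
        s_boundary=s_boundary,
        beta_hat={c: float(b) for c, b in zip(spec.covariates, beta)},
        variance_hat={nm: float(np.exp(v)) for nm, v in zip(variance_names, log_var)},
        loglik=loglik,
        n_events=data.n_events,
        k_params=k,
        aicc=aicc_val,
        converged=converged,
        params=theta,
    )


# ---------------------------------------------------------------------------
# profile confidence intervals and LRT


def _profile_nll(
    fixed_index: int, value: float, spec: ModelSpec, data: OadaData, theta_hat: np.ndarray
) -> float:
    """Re-optimize all parameters but one, held at ``value``."""
    X = data.X(spec.covariates)
    p = X.shape[1]
    free_idx = [i for i in range(len(theta_hat)) if i != fixed_index]
    bounds_all = _bounds(spec, p)

    def obj(free):
        theta = np.empty(len(theta_hat))
        theta[fixed_index] = value
        theta[free_idx] = free
        return marginal_negloglik(theta, spec, data)

    if not free_idx:
        return obj(np.empty(0))
    res = optimize.minimize(
        obj,
        theta_hat[free_idx],
        method="L-BFGS-B",
        bounds=[bounds_all[i] for i in free_idx],
        options={"ftol": 1e-12, "maxiter": 400},
    )
    return float(res.fun)


def profile_ci(
    spec: ModelSpec,
    data: OadaData | DiffusionSet,
    fit: FitResult,
    parameter: str,
    level: float = 0.95,
    networks=None,
    roster=None,
    max_expand: int = 40,
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for one named parameter.

    Bounds solve 2*(logL_max - logL_profile(theta)) = chi2_1(level),
    re-optimizing all other parameters.  For s parameters the lower
    bound is clipped at 0 (reported as exactly 0 when the likelihood
    does not drop below the threshold before the boundary); a side where
    the profile never drops within the search range is returned
    open-ended (+/- inf).
    """
    if not fit.converged:
        raise ValueError("cannot profile a non-converged fit")
    if not isinstance(data, OadaData):
        data = build_oada_data(data, networks, roster, pooling=spec.pooling)
    names = spec.param_names()
    if parameter not in names:
        raise KeyError(f"unknown parameter {parameter!r}; have {names}")
    idx = names.index(parameter)
    theta_hat = fit.params
    is_s = idx < spec.n_s
    return likelihood_interval(
        lambda v: _profile_nll(idx, v, spec, data, theta_hat),
        center=float(theta_hat[idx]),
        nll_min=-fit.loglik,
        level=level,
        lower_bound=0.0 if is_s else None,
        max_expand=max_expand,
    )


def likelihood_interval(
    profile_nll,
    center: float,
    nll_min: float,
    level: float = 0.95,
    lower_bound: float | None = None,
    max_expand: int = 40,
) -> tuple[float, float]:
    """Invert a (profile) negative log-likelihood into a likelihood-ratio
    confidence interval: the bounds solve
    2*(profile_nll(theta) - nll_min) = chi2_1(level).

    ``lower_bound`` clips the left endpoint (used for s >= 0; reported as
    exactly the bound when the profile never crosses the threshold before
    it).  A side where the profile never drops within the search range is
    returned open-ended (+/- inf).
    """
    crit = float(stats.chi2.ppf(level, 1))

    def g(value: float) -> float:
        return 2.0 * (profile_nll(value) - nll_min) - crit

    step0 = max(0.25 * abs(center), 0.25)

    def search(direction: float) -> float:
        prev = center  # g at the MLE is -crit (< 0)
        step = step0
        for _ in range(max_expand):
            cand = center + direction * step
            clipped = lower_bound is not None and cand < lower_bound
            if clipped:
                cand = lower_bound
            val = g(cand)
            if val >= 0:
                a, b = sorted((prev, cand))
                return float(optimize.brentq(g, a, b, xtol=1e-6, rtol=1e-8))
            if clipped:
                return lower_bound  # profile never drops before the boundary
            prev = cand
            step *= 1.8
        return float("-inf") if direction < 0 else float("inf")

    return (search(-1.0), search(+1.0))


def lrt_vs_asocial(fit_social: FitResult, fit_asocial: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of a social model against its asocial
    counterpart (same covariates and random effects, s removed)."""
    if fit_social.spec.covariates != fit_asocial.spec.covariates:
        raise ValueError("covariate sets differ between social and asocial fits")
    if fit_social.spec.random_effects != fit_asocial.spec.random_effects:
        raise ValueError("random-effect structures differ")
    if fit_asocial.spec.n_s != 0:
        raise ValueError("reference fit is not asocial")
    df = fit_social.spec.n_s
    chi2 = max(0.0, 2.0 * (fit_social.loglik - fit_asocial.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df else 1.0
    return chi2, df, p
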