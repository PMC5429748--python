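"""Resampling group statistics: Monte-Carlo ("approximative")
stratified permutation tests, the exact two-sided binomial test, and
per-patch descriptive summaries.

The permutation tests mirror the approximative (Monte-Carlo) tests of
the `coin` framework: a linear rank statistic, a null distribution of
B random within-stratum rearrangements (default B = 19999), a Z score
standardized by the resample mean and SD, and the add-one p-value
estimate (b + 1)/(B + 1), which guarantees p >= 1/(B + 1) and validity
at any B.  `exhaustive=True` switches to complete enumeration (exact p,
no add-one) on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .networks import BIRD, FLOCK
from .oada import DiffusionSet

__all__ = [
    "PermutationTestResult",
    "signed_rank_pratt_mc",
    "mwu_stratified_mc",
    "spearman_stratified_mc",
    "exact_binomial_two_sided",
    "patch_descriptives",
]

DEFAULT_B = 19999
_EPS = 1e-12


@dataclass
class PermutationTestResult:
    statistic: float  # raw linear statistic T
    statistic_z: float  # (T - mean(T*)) / sd(T*)
    p_value: float
    n_resamples: int  # B for Monte-Carlo, the enumeration size if exhaustive
    seed: int | None
    method: str  # "mc" | "exhaustive"


def _finish(T: float, T_null: np.ndarray, seed, method: str) -> PermutationTestResult:
    # two-sided on deviations from the resample mean: the linear statistic
    # need not be centered at zero (e.g. stratified rank sums)
    mean, sd = T_null.mean(), T_null.std(ddof=0)
    z = 0.0 if sd <= _EPS else (T - mean) / sd
    hits = int(np.sum(np.abs(T_null - mean) >= abs(T - mean) - _EPS))
    if method == "mc":
        p = (hits + 1) / (len(T_null) + 1)
    else:
        p = hits / len(T_null)
    return PermutationTestResult(
        statistic=float(T),
        statistic_z=float(z),
        p_value=float(min(1.0, p)),
        n_resamples=len(T_null),
        seed=seed,
        method=method,
    )


def signed_rank_pratt_mc(
    pairs,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Wilcoxon signed-rank test with Pratt zero handling, Monte-Carlo null.

    Differences are ranked by absolute value *including* zeros (mid-ranks
    for ties); zero differences are then discarded from the statistic
    T = sum of signed ranks.  The null flips the signs of the nonzero
    differences (B random flips, or all 2^m when ``exhaustive``).
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or not len(pairs):
        raise ValueError("pairs must be a nonempty (n, 2) array")
    d = pairs[:, 0] - pairs[:, 1]
    ranks = stats.rankdata(np.abs(d))  # zeros ranked, then dropped (Pratt)
    nz = d != 0
    if not nz.any():
        return PermutationTestResult(0.0, 0.0, 1.0, 0, seed, "degenerate")
    r = ranks[nz]
    T = float(np.sum(np.sign(d[nz]) * r))
    m = len(r)
    if exhaustive:
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=m)))
        T_null = signs @ r
        return _finish(T, T_null, seed, "exhaustive")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(B, m))
    return _finish(T, signs @ r, seed, "mc")


def _strata_groups(strata) -> list[np.ndarray]:
    strata = np.asarray(strata)
    return [np.flatnonzero(strata == s) for s in pd.unique(strata)]


def mwu_stratified_mc(
    values,
    group_labels,
    strata,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationTestResult:
    """Stratified Wilcoxon-Mann-Whitney test, Monte-Carlo null.

    Ranks are computed within strata (mid-ranks for ties); the statistic
    is the summed rank of the first group; the null shuffles group labels
    independently within each stratum.  A stratum containing only one
    group contributes no permutation variance.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    ulab = pd.unique(labels)
    if len(ulab) != 2:
        raise ValueError(f"need exactly two group labels, got {list(ulab)}")
    focal = labels == sorted(map(str, ulab))[0] if ulab.dtype.kind in "OU" else labels == ulab.min()
    groups = _strata_groups(strata)
    if not any(focal[g].any() and (~focal[g]).any() for g in groups):
        raise ValueError("no stratum contains both groups")

    per_stratum = []  # (ranks, focal mask) per stratum
    T = 0.0
    for g in groups:
        r = stats.rankdata(values[g])
        f = focal[g]
        T += float(r[f].sum())
        per_stratum.append((r, f))

    if exhaustive:
        T_null = np.zeros(1)
        for r, f in per_stratum:
            perms = np.array(
                [r[list(p)][: f.sum()].sum() for p in itertools.permutations(range(len(r)))]
            )
            T_null = (T_null[:, None] + perms[None, :]).ravel()
        return _finish(T, T_null, seed, "exhaustive")

    rng = np.random.default_rng(seed)
    T_null = np.zeros(B)
    for r, f in per_stratum:
        k = int(f.sum())
        if k == 0 or k == len(r):
            T_null += r[f].sum()  # constant: no permutation variance here
            continue
        order = np.argsort(rng.random((B, len(r))), axis=1)
        T_null += np.take(r, order[:, :k]).sum(axis=1)
    return _finish(T, T_null, seed, "mc")


def spearman_stratified_mc(
    x,
    y,
    strata,
    B: int = DEFAULT_B,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, PermutationTestResult]:
    """Stratified Spearman correlation test, Monte-Carlo null.

    r_S is the correlation of within-stratum (mid-)ranks, centered within
    strata; the null permutes y within strata.  Returns (r_S, test result)
    where the permuted statistic is the cross-product sum underlying r_S.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    groups = _strata_groups(strata)
    rx = np.empty(len(x))
    ry = np.empty(len(y))
    for g in groups:
        rx[g] = stats.rankdata(x[g]) - (len(g) + 1) / 2.0
        ry[g] = stats.rankdata(y[g]) - (len(g) + 1) / 2.0
    denom = math.sqrt(float(np.sum(rx**2)) * float(np.sum(ry**2)))
    if denom <= 0:
        raise ValueError("x or y is constant within every stratum: r_S undefined")
    T = float(np.sum(rx * ry))
    r_s = T / denom

    if exhaustive:
        T_null = np.zeros(1)
        for g in groups:
            perms = np.array(
                [np.dot(rx[g], ry[g][list(p)]) for p in itertools.permutations(range(len(g)))]
            )
            T_null = (T_null[:, None] + perms[None, :]).ravel()
        return r_s, _finish(T, T_null, seed, "exhaustive")

    rng = np.random.default_rng(seed)
    T_null = np.zeros(B)
    for g in groups:
        order = np.argsort(rng.random((B, len(g))), axis=1)
        T_null += np.take(ry[g], order) @ rx[g]
    return r_s, _finish(T, T_null, seed, "mc")


def exact_binomial_two_sided(x: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test, minimum-likelihood method.

    p = sum of Binomial(n, p0) point probabilities over all outcomes k
    whose probability does not exceed that of the observed x (within a
    1e-7 relative tolerance)."""
    if not (0 <= x <= n) or n < 1:
        raise ValueError("need 0 <= x <= n with n >= 1")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must lie strictly between 0 and 1")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    cutoff = pmf[x] * (1.0 + 1e-7)
    if cutoff >= pmf.max():  # observed outcome is the mode
        return 1.0
    return float(min(1.0, pmf[pmf <= cutoff].sum()))


def patch_descriptives(
    diffusions: DiffusionSet, extras: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean +/- sample SD (ddof=1) of per-flock patch measures, by patch rank.

    Built-in measures: first-feeder discovery time, discovery time of an
    average (acquiring) bird, and the number of naive birds that
    discovered the patch; flocks in which a patch was never exploited
    are excluded from the time summaries for that patch.  ``extras``
    (columns flock_id, patch_rank, <measure>...) appends e.g. first
    approach times, seed mass taken or aggression counts.
    """
    rows = []
    for d in diffusions:
        lat = [t for _, t in d.acquisitions]
        rows.append(
            {
                FLOCK: d.flock,
                "patch_rank": d.patch_rank,
                "first_feeder_time_s": min(lat) if lat else np.nan,
                "mean_bird_time_s": float(np.mean(lat)) if lat else np.nan,
                "n_birds_discovered": len(lat),
            }
        )
    per_flock = pd.DataFrame(rows)
    if extras is not None:
        per_flock = per_flock.merge(extras, on=[FLOCK, "patch_rank"], how="left")
    measures = [c for c in per_flock.columns if c not in (FLOCK, "patch_rank")]
    out = {}
    for rank, grp in per_flock.groupby("patch_rank"):
        out[rank] = {
            m: (float(grp[m].mean()), float(grp[m].std(ddof=1))) for m in measures
        }
    table = pd.DataFrame(
        {
            f"patch_{rank}": {m: f"{mu:.2f} ± {sd:.2f}" for m, (mu, sd) in vals.items()}
            for rank, vals in out.items()
        }
    )
    table.attrs["raw"] = out
    return table
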