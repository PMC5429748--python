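"""Shared brute-force oracles for the OADA likelihood tests.

These are deliberately independent of the package's vectorized
implementation: exposures, covariate encodings and per-event ratios are
recomputed with plain python loops.
"""

import numpy as np
import pandas as pd

import flocknbda as fn
from flocknbda.networks import FollowingNetwork


def random_instance(rng, n_birds=4, n_events=3, n_informed=1, covariate=True):
    """A tiny single-flock problem for enumeration oracles."""
    birds = [f"B{k}" for k in range(n_birds)]
    adj = rng.gamma(1.0, 2.0, size=(n_birds, n_birds))
    np.fill_diagonal(adj, 0.0)
    net = FollowingNetwork("F1", birds, adj, 1.0)
    informed = birds[:n_informed]
    naive = birds[n_informed:]
    order = list(rng.permutation(naive))
    n_events = min(n_events, len(naive))
    times = np.sort(rng.uniform(10, 1000, size=n_events))
    acq = list(zip(order[:n_events], times))
    roster = pd.DataFrame(
        {
            "bird_id": birds,
            "flock_id": "F1",
            "sex": [("M" if rng.random() < 0.5 else "F") for _ in birds],
            "age": rng.uniform(1, 6, size=n_birds).round(1),
            "informed": [b in informed for b in birds],
            "feeding_activity": rng.integers(5, 60, size=n_birds),
            "transmission_weight": rng.uniform(0.3, 1.0, size=n_birds),
        }
    )
    # make the flock maximum weight exactly 1
    roster.loc[roster["transmission_weight"].idxmax(), "transmission_weight"] = 1.0
    diff = fn.Diffusion(
        flock="F1",
        patch_rank=int(rng.integers(1, 3)),
        acquisitions=acq,
        censored=frozenset(order[n_events:]),
        demonstrators=frozenset(informed),
    )
    return diff, {"following": {"F1": net}}, roster


def enumeration_negloglik(diff, nets, roster, spec, s_free, beta):
    """Independent brute-force oracle: per-event next-acquirer ratios by
    direct python loops over the risk set (no shared code with the
    vectorized likelihood)."""
    net = nets["following"][diff.flock]
    w = dict(zip(roster["bird_id"], roster["transmission_weight"]))
    sexes = dict(zip(roster["bird_id"], roster["sex"]))
    ages = dict(zip(roster["bird_id"], roster["age"]))
    fa = dict(zip(roster["bird_id"], roster["feeding_activity"]))
    fa_all = np.array([fa[b] for b in roster["bird_id"]], dtype=float)
    mu, sd = fa_all.mean(), fa_all.std(ddof=0)

    def xvec(b):
        out = []
        for c in spec.covariates:
            if c == "sex":
                out.append(1.0 if sexes[b] == "M" else 0.0)
            elif c == "age":
                out.append(ages[b])
            else:
                out.append((fa[b] - mu) / sd if sd > 0 else 0.0)
        return np.array(out)

    mult = spec.s_multipliers(diff.patch_rank)
    s_patch = float(mult @ np.asarray(s_free)) if spec.n_s else 0.0
    status = {b: 1 for b in diff.demonstrators}
    at_risk = set(diff.naive)
    nll = 0.0
    for bird, _t in diff.acquisitions:
        lams = {}
        for r in sorted(at_risk):
            T = sum(
                net.weight(r, j) * w[j] * status.get(j, 0)
                for j in net.nodes
                if j != r
            )
            lams[r] = np.exp(float(np.dot(beta, xvec(r)))) * (1.0 + s_patch * T)
        nll -= np.log(lams[bird] / sum(lams.values()))
        at_risk.discard(bird)
        status[bird] = 1
    return nll
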