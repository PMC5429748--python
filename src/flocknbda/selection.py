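"""Model grid enumeration, AICc ranking, Akaike weights and support.

The candidate set crosses every covariate subset with the five
social-transmission scenarios and the two network types; asocial models
are network-free, so they are fitted once per covariate subset and
excluded from the per-network support sums.  Inference rests on the
"best models" set (entries within a Delta-AICc threshold of the best
model, 4 by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .oada import (
    COVARIATES,
    DiffusionSet,
    FitResult,
    ModelSpec,
    OadaData,
    SCENARIOS,
    build_oada_data,
    fit_oada,
)

__all__ = [
    "enumerate_models",
    "aicc",
    "akaike_weights",
    "fit_model_grid",
    "category_support",
    "best_models_set",
    "GridEntry",
    "ModelGridResult",
]


def enumerate_models(
    covariates: Sequence[str] = COVARIATES,
    scenarios: Sequence[str] = tuple(SCENARIOS),
    network_types: Sequence[str] = ("following", "homogeneous"),
    random_effects: str = "none",
    pooling: str = "pool_flocks_within_patch",
) -> list[ModelSpec]:
    """All combinations of covariate subset x scenario x network type.

    The network is irrelevant when s = 0, so asocial specs are collapsed
    across network types (network_type=None), giving, at the defaults,
    8 x (4 x 2 + 1) = 72 unique models.
    """
    if not scenarios or not network_types:
        raise ValueError("scenarios and network_types must be nonempty")
    subsets = [
        tuple(c)
        for r in range(len(covariates) + 1)
        for c in itertools.combinations(covariates, r)
    ]
    specs: list[ModelSpec] = []
    for cov in subsets:
        for scen in scenarios:
            if scen == "asocial":
                specs.append(
                    ModelSpec(
                        network_type=None,
                        scenario=scen,
                        covariates=cov,
                        random_effects=random_effects,
                        pooling=pooling,
                    )
                )
            else:
                for nt in network_types:
                    specs.append(
                        ModelSpec(
                            network_type=nt,
                            scenario=scen,
                            covariates=cov,
                            random_effects=random_effects,
                            pooling=pooling,
                        )
                    )
    assert len(specs) == len(set(specs))
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion corrected for small samples:
    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: Iterable[float]) -> np.ndarray:
    """Normalized relative support w_m = exp(-Delta_m/2) / sum exp(-Delta/2)."""
    a = np.asarray(list(aicc_values), dtype=float)
    if not np.isfinite(a).all():
        raise ValueError("AICc values must be finite")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class GridEntry:
    spec: ModelSpec
    fit: FitResult
    aicc: float
    delta_aicc: float = np.nan
    akaike_weight: float = np.nan


@dataclass
class ModelGridResult:
    entries: list[GridEntry]  # converged fits, ranked by AICc
    excluded: list[GridEntry] = field(default_factory=list)  # non-converged

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.aicc)
        if self.entries:
            best = self.entries[0].aicc
            w = akaike_weights([e.aicc for e in self.entries])
            for e, wi in zip(self.entries, w):
                e.delta_aicc = e.aicc - best
                e.akaike_weight = float(wi)

    @property
    def best(self) -> GridEntry:
        return self.entries[0]


def fit_model_grid(
    specs: Sequence[ModelSpec],
    diffusions: DiffusionSet,
    networks: Mapping[str, Mapping],
    roster,
    verbose: bool = False,
) -> ModelGridResult:
    """Fit every spec and rank by AICc; non-converged fits are excluded
    from ranking and weights (kept under ``excluded``)."""
    poolings = {s.pooling for s in specs}
    data_by_pooling = {
        p: build_oada_data(diffusions, networks, roster, pooling=p) for p in poolings
    }
    entries, excluded = [], []
    for spec in specs:
        fit = fit_oada(spec, data_by_pooling[spec.pooling])
        entry = GridEntry(spec=spec, fit=fit, aicc=fit.aicc)
        (entries if fit.converged and np.isfinite(fit.aicc) else excluded).append(entry)
        if verbose:
            state = "ok" if fit.converged else "EXCLUDED (non-converged)"
            print(f"  {spec.scenario:15s} {str(spec.network_type):12s} "
                  f"cov={','.join(spec.covariates) or '-'} AICc={fit.aicc:9.3f} {state}")
    return ModelGridResult(entries=entries, excluded=excluded)


def category_support(grid: ModelGridResult) -> dict:
    """Summed Akaike weights per scenario category and per network type,
    as percentages.  Asocial support is reported separately and does not
    count toward any network type; the following/homogeneous support
    ratio is rounded to 2 decimals (as are the percentages)."""
    by_cat: dict[str, float] = {}
    by_net: dict[str, float] = {}
    asocial = 0.0
    for e in grid.entries:
        by_cat[e.spec.scenario] = by_cat.get(e.spec.scenario, 0.0) + e.akaike_weight
        if e.spec.scenario == "asocial":
            asocial += e.akaike_weight
        else:
            by_net[e.spec.network_type] = (
                by_net.get(e.spec.network_type, 0.0) + e.akaike_weight
            )
    pct = lambda x: round(100.0 * x, 2)
    out = {
        "by_category_pct": {c: pct(w) for c, w in sorted(by_cat.items())},
        "by_network_pct": {n: pct(w) for n, w in sorted(by_net.items())},
        "asocial_pct": pct(asocial),
    }
    f, h = by_net.get("following", 0.0), by_net.get("homogeneous", 0.0)
    if h > 0:
        out["support_ratio_following_vs_homogeneous"] = round(f / h, 2)
    return out


def best_models_set(grid: ModelGridResult, delta: float = 4.0) -> list[GridEntry]:
    """Entries within ``delta`` AICc of the best-fitting model."""
    return [e for e in grid.entries if e.delta_aicc <= delta]
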