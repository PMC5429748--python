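"""Ranked-grid tables and figures.

`grid_to_frame` writes the machine-readable ranking (numeric columns,
round-trippable); `render_estimates_table` renders the human-readable
per-category table with "estimate [lo-hi]" strings, boundary estimates
as "constrained to 0" and absent covariates as an em dash.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .oada import COVARIATES, DiffusionSet
from .selection import GridEntry, ModelGridResult

EM_DASH = "—"

SCENARIO_LABELS = {
    "asocial": "No social transmission (asocial)",
    "shared_s": "Same social transmission rate at both patches",
    "separate_s": "Different social transmission rates at the two patches",
    "s_patch1_only": "Social transmission at the first patch only",
    "s_patch2_only": "Social transmission at the second patch only",
}


def grid_to_frame(grid: ModelGridResult) -> pd.DataFrame:
    """Numeric ranked-grid table (one row per converged model)."""
    rows = []
    for e in grid.entries:
        row = {
            "scenario": e.spec.scenario,
            "network_type": e.spec.network_type or "",
            "covariates": "+".join(e.spec.covariates),
            "random_effects": e.spec.random_effects,
            "loglik": e.fit.loglik,
            "k": e.fit.k_params,
            "n": e.fit.n_events,
            "aicc": e.aicc,
            "delta_aicc": e.delta_aicc,
            "akaike_weight": e.akaike_weight,
            "s1": e.fit.s_hat.get(1, np.nan),
            "s2": e.fit.s_hat.get(2, np.nan),
        }
        for c in COVARIATES:
            row[f"beta_{c}"] = e.fit.beta_hat.get(c, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _cell(value: float | None, ci: tuple[float, float] | None, boundary: bool) -> str:
    if value is None:
        return EM_DASH
    if boundary:
        return "constrained to 0"
    if ci is not None and all(np.isfinite(ci)):
        return f"{value:.3f} [{ci[0]:.3f}{ci[1]:.3f}]"
    return f"{value:.3f}"


def render_estimates_table(
    entries: list[GridEntry], fmt: str = "text"
) -> str:
    """Per-category blocks with AICc, delta AICc, weight and parameter
    cells "x.xxx [lo-hi]"; s estimates on the zero boundary render as
    "constrained to 0" and covariates absent from a model as an em dash.

    ``fmt`` is "text" (aligned) or "tsv".
    """
    header = ["model_category", "network", "AICc", "dAICc", "weight", "s1", "s2"] + [
        f"beta_{c}" for c in COVARIATES
    ]
    rows = []
    by_cat: dict[str, list[GridEntry]] = {}
    for e in entries:
        by_cat.setdefault(e.spec.scenario, []).append(e)
    for cat, group in by_cat.items():
        support = 100.0 * sum(e.akaike_weight for e in group)
        label = f"{SCENARIO_LABELS.get(cat, cat)} (support: {support:.2f}%)"
        for e in group:
            fit = e.fit
            cells = [
                label,
                e.spec.network_type or EM_DASH,
                f"{e.aicc:.2f}",
                f"{e.delta_aicc:.2f}",
                f"{e.akaike_weight:.2f}",
            ]
            for rank in (1, 2):
                if fit.spec.scenario == "asocial" or not fit.spec.s_multipliers(rank).any():
                    cells.append(EM_DASH if fit.spec.scenario == "asocial" else "constrained to 0")
                else:
                    cells.append(
                        _cell(
                            fit.s_hat[rank],
                            fit.profile_cis.get(f"s{rank}") or fit.profile_cis.get("s"),
                            fit.s_boundary[rank],
                        )
                    )
            for c in COVARIATES:
                if c in fit.spec.covariates:
                    cells.append(
                        _cell(fit.beta_hat[c], fit.profile_cis.get(f"beta:{c}"), False)
                    )
                else:
                    cells.append(EM_DASH)
            rows.append(cells)
            label = ""  # only label the first row of each block
    if fmt == "tsv":
        return "\n".join("\t".join(r) for r in [header] + rows) + "\n"
    widths = [max(len(str(r[i])) for r in [header] + rows) for i in range(len(header))]
    lines = [
        "  ".join(str(c).ljust(w) for c, w in zip(r, widths)).rstrip()
        for r in [header] + rows
    ]
    return "\n".join(lines) + "\n"


def plot_diffusion_curves(
    diffusions: DiffusionSet, censor_time_s: float, path=None
):
    """Per-flock step curves of cumulative discoverers over time, one
    panel per patch rank (the classic diffusion-curve display)."""
    ranks = sorted({d.patch_rank for d in diffusions})
    fig, axes = plt.subplots(1, len(ranks), figsize=(5 * len(ranks), 4), squeeze=False)
    for ax, rank in zip(axes[0], ranks):
        for d in (d for d in diffusions if d.patch_rank == rank):
            times = [0.0] + [t for _, t in d.acquisitions] + [censor_time_s]
            counts = [0] + list(range(1, len(d.acquisitions) + 1)) + [len(d.acquisitions)]
            ax.step(times, counts, where="post", alpha=0.7, label=d.flock)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("naive birds having fed")
        ax.set_title(f"Patch rank {rank}")
        ax.set_xlim(0, censor_time_s)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_strength_comparison(
    strengths: pd.DataFrame, first_feeders: set[str], path=None
):
    """Box plots of out- and in-strength for first-feeder birds versus
    their flock-mates."""
    s = strengths.assign(
        group=[
            "first-feeder" if b in first_feeders else "other"
            for b in strengths["bird_id"]
        ]
    )
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, metric in zip(axes, ["out_strength", "in_strength"]):
        data = [
            s.loc[s["group"] == g, metric].to_numpy()
            for g in ("first-feeder", "other")
        ]
        ax.boxplot(data, tick_labels=["first-feeder", "other"])
        ax.set_ylabel(f"{metric.replace('_', '-')} (followings/h)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
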