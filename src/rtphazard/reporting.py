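"""Tabular and graphical outputs plus the run manifest.

Every figure's underlying numbers are also written as CSV by the CLI layer;
plots here are presentation only. Negative raw hazards are clamped to zero at
this layer (and only here) for display.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .episodes import episode_summary
from .smoothing import HazardCurve, excess_half_time
from .survival import SurvivalCurve, daily_grid, median_survival

__all__ = [
    "RunManifest",
    "plot_survivor",
    "plot_risk_set",
    "plot_hazard_curves",
    "severity_position_table",
    "fit_summary",
]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, seed, counts, outputs."""

    seed: int | None = None
    config_hash: str | None = None
    inputs: list[str] = field(default_factory=list)
    row_counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    versions: dict[str, str] = field(
        default_factory=lambda: {
            "rtphazard": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
    )

    @staticmethod
    def hash_config(payload) -> str:
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def record_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def plot_survivor(curve: SurvivalCurve, path, median: float | None = None) -> None:
    """Step plot of the survivor function with its confidence band."""
    grid = daily_grid(curve)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.step(grid["day"], grid["S"], where="post", color="tab:blue", lw=1.5)
    ax.fill_between(
        grid["day"], grid["ci_lower"], grid["ci_upper"], step="post",
        alpha=0.25, color="tab:blue",
        label=f"{int(curve.ci_level * 100)}% CI",
    )
    if median is not None:
        ax.axvline(median, color="grey", ls="--", lw=1)
        ax.axhline(0.5, color="grey", ls=":", lw=1)
        ax.annotate(f"median = {median:.1f} d", (median, 0.52), fontsize=9)
    ax.set_xlabel("days after RTP")
    ax.set_ylabel("survival (no subsequent non-contact injury)")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="upper right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_risk_set(curve: SurvivalCurve, path, max_day: int = 100) -> None:
    """Bars of the number still at risk and of observed events per day."""
    grid = daily_grid(curve, max_day=max_day)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    ax1.bar(grid["day"], grid["n_at_risk"], width=1.0, color="tab:green")
    ax1.set_ylabel("at risk")
    ax2.bar(grid["day"], grid["n_events"], width=1.0, color="tab:red")
    ax2.set_ylabel("observed events")
    ax2.set_xlabel("days after RTP")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_hazard_curves(curves: dict[str, HazardCurve], path, title: str = "") -> None:
    """Overlayed continuous hazard curves (display-clamped at zero)."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, c in curves.items():
        ax.plot(c.days, c.clamped(), lw=1.5, label=label)
    ax.set_xlabel("days after RTP")
    ax.set_ylabel("hazard (per day)")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def severity_position_table(episodes: pd.DataFrame, observed_only: bool = True) -> pd.DataFrame:
    """Cross-tabulation of index-injury severity by playing position."""
    sub = episodes[episodes["event"]] if observed_only else episodes
    return pd.crosstab(sub["index_severity"], sub["position"])


def fit_summary(
    episodes: pd.DataFrame,
    curve: SurvivalCurve,
    hazard: HazardCurve,
    plateau_window: tuple[int, int] | None = None,
) -> dict:
    """Headline quantities of one fitted pipeline run.

    The plateau defaults to the last 40% of the fitted window (days 60-100
    for the standard 100-day window).
    """
    if plateau_window is None:
        w = int(hazard.days.max())
        plateau_window = (int(round(0.6 * w)), w)
    in_plateau = (hazard.days >= plateau_window[0]) & (hazard.days <= plateau_window[1])
    plateau = float(hazard.hazard[in_plateau].mean())
    half_time = excess_half_time(hazard, plateau_window)
    summary = episode_summary(episodes)
    med = median_survival(curve)
    return {
        "episodes": {k: summary[k] for k in ("n_episodes", "n_observed", "n_censored", "censor_reasons")},
        "median_survival_days": med,
        "hazard_day1": float(hazard.hazard[0]),
        "plateau_hazard": plateau,
        "day1_over_plateau": float(hazard.hazard[0]) / plateau if plateau > 0 else None,
        "excess_half_time_days": half_time,
        "n_negative_hazard_days": int(hazard.negative_flag.sum()),
    }
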