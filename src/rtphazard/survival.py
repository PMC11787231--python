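"""From-scratch Kaplan-Meier estimation at daily granularity.

The product-limit survival estimate, its Greenwood variance with
complementary-log-log confidence bands, the cumulative hazard
``H(t) = -ln S(t)``, and the linear-interpolation median survival time are all
implemented directly (no survival library in the computation path), because
the exactness of these quantities is what the downstream hazard smoothing
rests on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalCurve",
    "CumHazardCurve",
    "km_fit",
    "greenwood_band",
    "cumulative_hazard",
    "median_survival",
    "daily_grid",
    "write_curve_csv",
]


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function over the distinct observed days.

    At tied days events are processed before censorings: both leave the risk
    set after the day, but only events move the survival estimate.
    """

    times: np.ndarray  # sorted distinct day values
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_level: float = 0.95
    all_censored: bool = False
    greenwood_var: np.ndarray = field(default=None, repr=False)

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous step value of S at arbitrary times (S=1 before the first)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx >= 0, self.survival[np.maximum(idx, 0)], 1.0)
        return s


@dataclass
class CumHazardCurve:
    """Cumulative hazard ``H(t) = -ln S(t)`` on the curve's day values."""

    times: np.ndarray
    cum_hazard: np.ndarray

    def at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        return np.where(idx >= 0, self.cum_hazard[np.maximum(idx, 0)], 0.0)


def km_fit(episodes, ci_level: float = 0.95) -> SurvivalCurve:
    """Product-limit estimate from an episode table (or time/event arrays).

    ``episodes`` is either a DataFrame with ``time_days`` and ``event`` columns
    or a ``(times, events)`` pair. S changes only at event days; censored-only
    days shrink the risk set without moving S.
    """
    if isinstance(episodes, pd.DataFrame):
        t = episodes["time_days"].to_numpy(dtype=float)
        e = episodes["event"].to_numpy(dtype=bool)
    else:
        t, e = episodes
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit requires at least one episode")
    if np.any(t < 1):
        raise ValueError("episode durations must be >= 1 day")

    times = np.unique(t)
    d = np.array([(e & (t == tj)).sum() for tj in times], dtype=float)
    c = np.array([(~e & (t == tj)).sum() for tj in times], dtype=float)
    n = t.size - np.concatenate(([0.0], np.cumsum(d + c)[:-1]))

    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(n > 0, 1.0 - d / n, 1.0)
    surv = np.cumprod(factors)

    all_censored = not e.any()
    if all_censored:
        warnings.warn("all episodes censored: S is identically 1", stacklevel=2)

    curve = SurvivalCurve(
        times=times,
        n_at_risk=n.astype(int),
        n_events=d.astype(int),
        n_censored=c.astype(int),
        survival=surv,
        ci_lower=surv.copy(),
        ci_upper=surv.copy(),
        ci_level=ci_level,
        all_censored=all_censored,
    )
    return greenwood_band(curve, ci_level)


def greenwood_band(curve: SurvivalCurve, level: float = 0.95) -> SurvivalCurve:
    """Pointwise confidence band from the Greenwood variance.

    ``Var[S(t)] = S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))``; the band
    is computed on the log(-log S) scale so it respects [0, 1], and collapses
    to the point estimate wherever S is exactly 0 or 1.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    d = curve.n_events.astype(float)
    n = curve.n_at_risk.astype(float)
    s = curve.survival
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where((d > 0) & (n > d), d / (n * (n - d)), np.where(d >= n, np.inf, 0.0))
    gsum = np.cumsum(terms)
    var = s**2 * gsum
    z = stats.norm.ppf(0.5 + level / 2.0)
    lower = s.copy()
    upper = s.copy()
    interior = (s > 0.0) & (s < 1.0) & np.isfinite(var)
    if interior.any():
        si = s[interior]
        se_cloglog = np.sqrt(var[interior]) / (si * np.abs(np.log(si)))
        theta = np.exp(z * se_cloglog)
        lower[interior] = si**theta
        upper[interior] = si ** (1.0 / theta)
    curve.ci_lower = np.clip(lower, 0.0, 1.0)
    curve.ci_upper = np.clip(upper, 0.0, 1.0)
    curve.ci_level = level
    curve.greenwood_var = var
    return curve


def cumulative_hazard(curve: SurvivalCurve) -> CumHazardCurve:
    """``H(t_j) = -ln S(t_j)``; points where S has hit 0 are dropped with a warning."""
    keep = curve.survival > 0.0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} point(s) where S=0 (H undefined)",
            stacklevel=2,
        )
    return CumHazardCurve(
        times=curve.times[keep],
        cum_hazard=-np.log(curve.survival[keep]),
    )


def median_survival(curve: SurvivalCurve) -> float | None:
    """Median survival by linear interpolation on the unit-day grid.

    With ``m`` the last integer day at which S is still above 0.5,
    ``T = m + (S(m) - 0.5) / (S(m) - S(m+1))``. Returns None when S never
    falls to 0.5.
    """
    if curve.survival.min() > 0.5:
        return None
    max_day = int(curve.times.max())
    days = np.arange(0, max_day + 1)
    s_daily = curve.survival_at(days)
    below = np.nonzero(s_daily <= 0.5)[0]
    first_below = below[0]
    if first_below == 0:  # S drops at day values < 1 cannot occur (times >= 1)
        return 0.0
    m = first_below - 1
    s_m, s_m1 = s_daily[m], s_daily[first_below]
    return float(m + (s_m - 0.5) / (s_m - s_m1))


def daily_grid(curve: SurvivalCurve, max_day: int | None = None) -> pd.DataFrame:
    """Expand the step curve to one row per integer day 0..max_day.

    S, bands and H carry the right-continuous step value; event/censor counts
    are per-day (zero on days without transitions). Gives downstream fitting
    exactly one response point per day.
    """
    if max_day is None:
        max_day = int(curve.times.max())
    days = np.arange(0, max_day + 1)
    idx = np.searchsorted(curve.times, days, side="right") - 1

    def step(values, before):
        return np.where(idx >= 0, np.asarray(values)[np.maximum(idx, 0)], before)

    n0 = int(curve.n_at_risk[0]) if curve.n_at_risk.size else 0
    remaining = curve.n_at_risk - curve.n_events - curve.n_censored
    s = step(curve.survival, 1.0)
    out = pd.DataFrame(
        {
            "day": days,
            "n_at_risk": step(remaining, n0).astype(int),
            "n_events": 0,
            "n_censored": 0,
            "S": s,
            "ci_lower": step(curve.ci_lower, 1.0),
            "ci_upper": step(curve.ci_upper, 1.0),
        }
    )
    day_pos = {int(tj): j for j, tj in enumerate(curve.times)}
    for day, j in day_pos.items():
        if 0 <= day <= max_day:
            out.loc[day, "n_events"] = int(curve.n_events[j])
            out.loc[day, "n_censored"] = int(curve.n_censored[j])
    with np.errstate(divide="ignore"):
        out["H"] = np.where(s > 0, -np.log(s), np.inf)
    return out


def write_curve_csv(curve: SurvivalCurve, path, max_day: int | None = None) -> None:
    daily_grid(curve, max_day=max_day).to_csv(path, index=False)
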