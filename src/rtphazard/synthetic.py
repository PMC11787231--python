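"""Synthetic multi-season injury/RTP cohort generator with known ground-truth hazard.

The generator emulates a professional-football injury register: players get
injured, rehabilitate for a severity-dependent number of days, return to play
(RTP), and are then exposed to an elevated, decaying hazard of the next injury.
Because the generating hazard is known in closed form, every downstream stage
(episode construction, Kaplan-Meier fit, cumulative-hazard smoothing) can be
validated against ground truth.

Time is discrete at the day level: on each in-season day an at-risk player
suffers an injury with probability ``frailty_i * h(t)`` where ``t`` is days
since the player's last RTP (or the baseline rate before any injury).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "POSITIONS",
    "SEVERITIES",
    "ExcessParams",
    "Season",
    "SimulationConfig",
    "default_calendar",
    "excess_hazard",
    "simulate_cohort",
    "write_records_csv",
    "read_records_csv",
]

POSITIONS = ("goalkeeper", "defender", "midfielder", "forward")
SEVERITIES = ("minimal", "mild", "moderate", "severe")

#: Squad composition of the emulated league cohort (players per position).
_POSITION_COUNTS = {
    "goalkeeper": 41,
    "defender": 236,
    "midfielder": 272,
    "forward": 141,
}

RECORD_COLUMNS = [
    "player_id",
    "position",
    "season",
    "injury_date",
    "rtp_date",
    "contact",
    "time_loss_days",
]


@dataclass(frozen=True)
class Season:
    """One football season: label, first day of exposure, date of last match."""

    label: str
    start: dt.date
    last_match: dt.date

    def __post_init__(self) -> None:
        if self.last_match <= self.start:
            raise ValueError(f"season {self.label}: last_match must follow start")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day <= self.last_match


def default_calendar() -> list[Season]:
    """Four seasons with 1 August starts and the league's last-match dates."""
    return [
        Season("2014/15", dt.date(2014, 8, 1), dt.date(2015, 5, 23)),
        Season("2015/16", dt.date(2015, 8, 1), dt.date(2016, 5, 14)),
        Season("2016/17", dt.date(2016, 8, 1), dt.date(2017, 5, 20)),
        Season("2017/18", dt.date(2017, 8, 1), dt.date(2018, 5, 12)),
    ]


@dataclass(frozen=True)
class ExcessParams:
    """Shape of the post-RTP excess hazard for one index-severity category.

    family
        ``"exp_decay"``: excess decays geometrically from its maximum at RTP,
        ``h(t) = lam0 * (1 + amplitude * 2**(-t/half_time))``.
        ``"delayed_peak"``: excess ramps up, peaks after a delay, then decays,
        ``h(t) = lam0 * (1 + amplitude * (t/d) * exp(1 - t/d) * 2**(-t/half_time))``;
        the ramp factor equals 1 at ``t = d`` so ``amplitude`` remains the
        peak excess scale, and ``h(0) = lam0`` exactly.
    amplitude
        Peak excess as a multiple of baseline (``e >= 0``).
    half_time
        Days for the geometric decay factor to halve (``tau > 0``).
    peak_delay
        Days to the ramp maximum (``d > 0``; only used by ``delayed_peak``).
    """

    family: str = "exp_decay"
    amplitude: float = 1.0
    half_time: float = 25.0
    peak_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("exp_decay", "delayed_peak"):
            raise ValueError(f"unknown excess family {self.family!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.half_time <= 0:
            raise ValueError("half_time must be > 0")
        if self.family == "delayed_peak" and self.peak_delay <= 0:
            raise ValueError("delayed_peak requires peak_delay > 0")


def excess_hazard(t, params: ExcessParams, baseline: float):
    """Per-day hazard ``h(t)`` at ``t`` days since RTP; ``h -> baseline`` as t grows.

    Accepts scalar or array ``t``; rejects negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("days since RTP must be >= 0")
    if baseline <= 0:
        raise ValueError("baseline hazard must be > 0")
    decay = 2.0 ** (-t_arr / params.half_time)
    if params.family == "exp_decay":
        h = baseline * (1.0 + params.amplitude * decay)
    else:  # delayed_peak
        d = params.peak_delay
        ramp = (t_arr / d) * np.exp(1.0 - t_arr / d)
        h = baseline * (1.0 + params.amplitude * ramp * decay)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(h)
    return h


def _default_position_weights() -> dict[str, float]:
    total = sum(_POSITION_COUNTS.values())
    return {pos: _POSITION_COUNTS[pos] / total for pos in POSITIONS}


def _default_excess() -> dict[str, ExcessParams]:
    return {sev: ExcessParams("exp_decay", 1.0, 25.0) for sev in SEVERITIES}


@dataclass
class SimulationConfig:
    """All generative parameters of the synthetic cohort.

    ``frailty_shape`` is the shape of a mean-1 gamma frailty multiplying each
    player's hazard (smaller shape = more heterogeneity); ``None`` disables
    frailty (every player's multiplier is exactly 1), which makes the stated
    hazard the exact population hazard -- the right setting for parameter
    recovery checks.
    """

    n_players: int = 800
    season_calendar: list[Season] = field(default_factory=default_calendar)
    position_weights: dict[str, float] = field(default_factory=_default_position_weights)
    frailty_shape: float | None = 2.0
    baseline_hazard: float = 0.005
    excess_params: dict[str, ExcessParams] = field(default_factory=_default_excess)
    contact_prob: float = 0.35
    severity_probs: dict[str, float] = field(
        default_factory=lambda: {
            "minimal": 0.389,
            "mild": 0.202,
            "moderate": 0.245,
            "severe": 0.164,
        }
    )
    severity_duration_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "minimal": (1, 3),
            "mild": (4, 7),
            "moderate": (8, 28),
            "severe": (29, 180),
        }
    )
    rng_seed: int | None = None

    @property
    def n_seasons(self) -> int:
        return len(self.season_calendar)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_players < 0:
            raise ValueError("n_players must be >= 0")
        if self.rng_seed is None:
            raise ValueError("rng_seed is required for reproducibility")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.contact_prob <= 1.0:
            raise ValueError("contact_prob must be in [0, 1]")
        if self.frailty_shape is not None and self.frailty_shape <= 0:
            raise ValueError("frailty_shape must be > 0 or None")
        for name, weights, keys in (
            ("position_weights", self.position_weights, POSITIONS),
            ("severity_probs", self.severity_probs, SEVERITIES),
        ):
            if set(weights) != set(keys):
                raise ValueError(f"{name} must have keys {keys}")
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} must be non-negative")
        if set(self.excess_params) != set(SEVERITIES):
            raise ValueError(f"excess_params must have keys {SEVERITIES}")
        for sev, (lo, hi) in self.severity_duration_ranges.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"severity_duration_ranges[{sev!r}]: need 1 <= lo <= hi")
        cal = self.season_calendar
        if not cal:
            raise ValueError("season_calendar must not be empty")
        for a, b in zip(cal, cal[1:]):
            if b.start <= a.last_match:
                raise ValueError("seasons must be chronologically ordered and non-overlapping")

    # -- config file round trip ------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["season_calendar"] = [
            {"label": s.label, "start": s.start.isoformat(), "last_match": s.last_match.isoformat()}
            for s in self.season_calendar
        ]
        d["excess_params"] = {k: dataclasses.asdict(v) for k, v in self.excess_params.items()}
        d["severity_duration_ranges"] = {
            k: list(v) for k, v in self.severity_duration_ranges.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "rng_seed" not in d or d["rng_seed"] is None:
            raise ValueError("config is missing required key 'rng_seed'")
        if "season_calendar" in d:
            d["season_calendar"] = [
                Season(
                    s["label"],
                    dt.date.fromisoformat(s["start"]),
                    dt.date.fromisoformat(s["last_match"]),
                )
                for s in d["season_calendar"]
            ]
        if "excess_params" in d:
            d["excess_params"] = {
                k: ExcessParams(**v) if not isinstance(v, ExcessParams) else v
                for k, v in d["excess_params"].items()
            }
        if "severity_duration_ranges" in d:
            d["severity_duration_ranges"] = {
                k: tuple(v) for k, v in d["severity_duration_ranges"].items()
            }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the cohort day by day and return one row per injury.

    Mechanics per player: a mean-1 gamma frailty is drawn once; before the
    first injury the daily injury probability is ``frailty * baseline``; after
    each RTP it is ``frailty * excess_hazard(days since RTP)`` with the excess
    shape of the *previous* (index) injury's severity; exposure resumes on the
    first day after the RTP date (days-since-RTP clock starts at 1). An injury
    removes the player from exposure for a uniformly drawn time-loss within
    its severity band; no injuries occur during the summer break, but calendar
    time (and hence the days-since-RTP clock) keeps running. Identical config (including
    seed) yields a byte-identical table.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    n = cfg.n_players
    pos_probs = np.array([cfg.position_weights[p] for p in POSITIONS])
    positions = rng.choice(len(POSITIONS), size=n, p=pos_probs)
    if cfg.frailty_shape is None:
        frailty = np.ones(n)
    else:
        frailty = rng.gamma(cfg.frailty_shape, 1.0 / cfg.frailty_shape, size=n)

    sev_cum = np.cumsum([cfg.severity_probs[s] for s in SEVERITIES])
    dur_lo = np.array([cfg.severity_duration_ranges[s][0] for s in SEVERITIES])
    dur_hi = np.array([cfg.severity_duration_ranges[s][1] for s in SEVERITIES])

    cal = cfg.season_calendar
    origin = cal[0].start
    horizon = (cal[-1].last_match - origin).days + 1
    # per-day season index, -1 during summer breaks
    season_of_day = np.full(horizon, -1, dtype=int)
    for si, season in enumerate(cal):
        a = (season.start - origin).days
        b = (season.last_match - origin).days
        season_of_day[a : b + 1] = si
    in_season_days = np.nonzero(season_of_day >= 0)[0]

    # player state
    next_available = np.zeros(n, dtype=int)  # first day index at risk again
    last_rtp = np.full(n, -1, dtype=int)  # day index of last RTP, -1 = never injured
    last_sev = np.full(n, -1, dtype=int)

    baseline = cfg.baseline_hazard
    records: list[tuple] = []
    for d in in_season_days:
        at_risk = next_available <= d
        if not at_risk.any():
            continue
        h = np.full(n, baseline)
        injured_before = at_risk & (last_rtp >= 0)
        for si, sev in enumerate(SEVERITIES):
            mask = injured_before & (last_sev == si)
            if mask.any():
                t_since = (d - last_rtp[mask]).astype(float)
                h[mask] = excess_hazard(t_since, cfg.excess_params[sev], baseline)
        p = np.clip(frailty * h, 0.0, 1.0)
        hit = at_risk & (rng.random(n) < p)
        if not hit.any():
            continue
        idx = np.nonzero(hit)[0]
        contact = rng.random(idx.size) < cfg.contact_prob
        sev_idx = np.searchsorted(sev_cum, rng.random(idx.size), side="right")
        sev_idx = np.minimum(sev_idx, len(SEVERITIES) - 1)
        time_loss = rng.integers(dur_lo[sev_idx], dur_hi[sev_idx] + 1)
        season_label = cal[season_of_day[d]].label
        injury_date = origin + dt.timedelta(days=int(d))
        for j, pi in enumerate(idx):
            records.append(
                (
                    f"P{pi:04d}",
                    POSITIONS[positions[pi]],
                    season_label,
                    injury_date,
                    injury_date + dt.timedelta(days=int(time_loss[j])),
                    bool(contact[j]),
                    int(time_loss[j]),
                )
            )
        # risk resumes the day after RTP: the first exposed day is t = 1 on
        # the days-since-RTP clock, matching the daily episode grid
        next_available[idx] = d + time_loss + 1
        last_rtp[idx] = d + time_loss
        last_sev[idx] = sev_idx

    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    if df.empty:
        df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            RECORD_COLUMNS, ["str", "str", "str", "object", "object", "bool", "int64"]
        )})
    return df


def write_records_csv(records: pd.DataFrame, path) -> None:
    out = records.copy()
    for col in ("injury_date", "rtp_date"):
        out[col] = out[col].map(lambda x: x.isoformat())
    out.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"player_id": str, "position": str, "season": str})
    for col in ("injury_date", "rtp_date"):
        df[col] = pd.to_datetime(df[col]).dt.date
    df["contact"] = df["contact"].astype(bool)
    df["time_loss_days"] = df["time_loss_days"].astype(int)
    return df
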