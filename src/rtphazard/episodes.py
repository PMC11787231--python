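"""Build censored return-to-play (RTP) episodes from raw injury records.

Each injury on a player's record is the index injury of one episode that starts
at its RTP date. The episode ends with the player's next injury if that injury
is non-contact and occurs in the same season as the RTP (an observed event).
Otherwise the episode is censored: at the next injury's date when that injury
is contact-related, or at the season's last-match date when no qualifying
injury occurs before the season ends (including when the next injury falls in
a later season, since summer exposure and minor-injury recording differ from
in-season conditions).
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .synthetic import Season

logger = logging.getLogger(__name__)

__all__ = [
    "SEVERITY_BOUNDS",
    "categorize_severity",
    "build_episodes",
    "episode_summary",
    "write_episodes_csv",
    "read_episodes_csv",
]

#: Time-loss day bounds per severity category (upper bound None = unbounded).
SEVERITY_BOUNDS: dict[str, tuple[int, int | None]] = {
    "minimal": (1, 3),
    "mild": (4, 7),
    "moderate": (8, 28),
    "severe": (29, None),
}

EPISODE_COLUMNS = [
    "player_id",
    "season",
    "rtp_date",
    "time_days",
    "event",
    "censor_reason",
    "index_severity",
    "position",
]


def categorize_severity(time_loss_days: int) -> str:
    """Map a time-loss duration in days to its severity category."""
    if time_loss_days < 1:
        raise ValueError("time_loss_days must be >= 1")
    for label, (lo, hi) in SEVERITY_BOUNDS.items():
        if time_loss_days >= lo and (hi is None or time_loss_days <= hi):
            return label
    raise AssertionError("severity bounds must partition the positive integers")


def _exposure_season(rtp_date: dt.date, calendar: list[Season]) -> Season | None:
    """Season in which post-RTP exposure takes place.

    An RTP during a season (strictly before its last match) is exposed in that
    season; an RTP during the summer break, or on/after a last-match date, is
    exposed in the following season (the days-since-RTP clock still starts at
    the actual RTP date). Returns None when no exposure remains.
    """
    for season in calendar:
        if rtp_date < season.last_match and rtp_date >= season.start:
            return season
        if rtp_date < season.start:
            return season
    return None


def build_episodes(records: pd.DataFrame, calendar: list[Season]) -> pd.DataFrame:
    """One censored episode per (index injury, RTP) pair.

    Records are chained greedily in date order within each player, so an injury
    can be both the subsequent injury of one episode and the index injury of
    the next. A subsequent injury on the RTP day itself is coded as day 1 (the
    daily grid cannot represent shorter intervals and dropping real events
    would bias the hazard downward). Episodes whose RTP leaves no remaining
    exposure in any configured season are dropped with a logged warning.
    """
    if records.empty:
        return pd.DataFrame(columns=EPISODE_COLUMNS).astype(
            {"time_days": "int64", "event": "bool"}, errors="ignore"
        )
    rec = records.sort_values(["player_id", "injury_date", "rtp_date"]).reset_index(
        drop=True
    )
    rtp_ord = rec["rtp_date"].map(dt.date.toordinal).to_numpy()
    inj_ord = rec["injury_date"].map(dt.date.toordinal).to_numpy()
    last_match_ord = np.array([s.last_match.toordinal() for s in calendar])
    labels = np.array([s.label for s in calendar])

    # exposure season: first season whose last match lies beyond the RTP date
    # (an RTP during the summer break is exposed in the following season; the
    # days-since-RTP clock still starts at the actual RTP date)
    season_idx = np.searchsorted(last_match_ord, rtp_ord, side="right")
    dropped = season_idx >= len(calendar)
    if dropped.any():
        for pid, rtp in zip(rec.loc[dropped, "player_id"], rec.loc[dropped, "rtp_date"]):
            logger.warning(
                "dropping episode for %s: RTP %s has no remaining season exposure",
                pid,
                rtp,
            )
        logger.warning("dropped %d episode(s) without season exposure", int(dropped.sum()))

    same_player = rec["player_id"].to_numpy()[1:] == rec["player_id"].to_numpy()[:-1]
    has_next = np.concatenate((same_player, [False]))
    next_inj_ord = np.concatenate((inj_ord[1:], [0]))
    next_contact = np.concatenate((rec["contact"].to_numpy()[1:], [False]))
    next_position = np.concatenate((rec["position"].to_numpy()[1:], [""]))
    overlap = has_next & (next_inj_ord < rtp_ord)
    if overlap.any():
        i = int(np.nonzero(overlap)[0][0])
        raise ValueError(
            f"player {rec['player_id'][i]}: injury on {rec['injury_date'][i + 1]} "
            f"overlaps rehabilitation ending {rec['rtp_date'][i]}"
        )

    keep = ~dropped
    si = np.minimum(season_idx, len(calendar) - 1)
    season_end_ord = last_match_ord[si]
    outcome_in_season = has_next & (next_inj_ord <= season_end_ord)
    # a subsequent injury on the RTP day itself is coded as day 1
    gap = np.maximum(1, next_inj_ord - rtp_ord)
    time_days = np.where(outcome_in_season, gap, season_end_ord - rtp_ord)
    event = outcome_in_season & ~next_contact
    reason = np.where(
        outcome_in_season,
        np.where(next_contact, "contact_injury", "none"),
        "season_end",
    )
    position = np.where(outcome_in_season, next_position, rec["position"].to_numpy())

    df = pd.DataFrame(
        {
            "player_id": rec["player_id"].to_numpy()[keep],
            "season": labels[si[keep]],
            "rtp_date": rec["rtp_date"].to_numpy()[keep],
            "time_days": time_days[keep].astype(int),
            "event": event[keep],
            "censor_reason": reason[keep],
            "index_severity": [
                categorize_severity(int(v))
                for v in rec["time_loss_days"].to_numpy()[keep]
            ],
            "position": position[keep],
        }
    )
    return df.reset_index(drop=True)


def episode_summary(episodes: pd.DataFrame) -> dict:
    """Accounting of an episode table: totals, censor reasons, cross-tabs."""
    if episodes.empty:
        return {
            "n_episodes": 0,
            "n_observed": 0,
            "n_censored": 0,
            "censor_reasons": {},
            "severity_by_position": {},
            "observed_severity_shares": {},
        }
    observed = episodes["event"].sum()
    reasons = (
        episodes.loc[~episodes["event"], "censor_reason"].value_counts().to_dict()
    )
    crosstab = (
        pd.crosstab(episodes["index_severity"], episodes["position"])
        .to_dict(orient="index")
    )
    ev = episodes[episodes["event"]]
    shares = (
        (ev["index_severity"].value_counts(normalize=True)).round(6).to_dict()
        if len(ev)
        else {}
    )
    return {
        "n_episodes": int(len(episodes)),
        "n_observed": int(observed),
        "n_censored": int(len(episodes) - observed),
        "censor_reasons": {k: int(v) for k, v in reasons.items()},
        "severity_by_position": crosstab,
        "observed_severity_shares": shares,
    }


def write_episodes_csv(episodes: pd.DataFrame, path) -> None:
    out = episodes.copy()
    out["rtp_date"] = out["rtp_date"].map(lambda x: x.isoformat())
    out["event"] = out["event"].astype(int)
    out.to_csv(path, index=False)


def read_episodes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"player_id": str, "season": str})
    df["rtp_date"] = pd.to_datetime(df["rtp_date"]).dt.date
    df["event"] = df["event"].astype(bool)
    df["time_days"] = df["time_days"].astype(int)
    return df
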