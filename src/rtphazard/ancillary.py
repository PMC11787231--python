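"""Robustness analyses around the main hazard-curve pipeline.

Three checks: a baseline comparator built from exposure beyond the first
100 post-RTP days (is the late "baseline" really time-constant?), up-/down-
sampling to probe the hierarchical structure (frequently injured players
contribute more episodes), and leave-one-quarter-out round-robin splitting at
the player level to probe overfitting by the high-degree polynomial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .smoothing import DEFAULT_DEGREE, DEFAULT_WINDOW, HazardCurve, pipeline_hazard

__all__ = [
    "baseline_comparator_episodes",
    "downsample_first_rtp",
    "upsample_to_max",
    "round_robin_split",
    "round_robin_curves",
]


def baseline_comparator_episodes(episodes: pd.DataFrame, offset: int = 100) -> pd.DataFrame:
    """Re-clock episodes to start ``offset`` days after RTP.

    Episodes that end at or before ``offset`` are excluded; the rest keep
    their outcome and censoring reason with ``time_days`` reduced by
    ``offset``. Running the unchanged pipeline on the result estimates the
    hazard outside the RTP context.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    out = episodes.loc[episodes["time_days"] > offset].copy()
    out["time_days"] = out["time_days"] - offset
    return out.reset_index(drop=True)


def downsample_first_rtp(episodes: pd.DataFrame) -> pd.DataFrame:
    """Keep only the earliest-RTP episode per (player, season)."""
    order = episodes.sort_values(["player_id", "season", "rtp_date"])
    return (
        order.groupby(["player_id", "season"], sort=False)
        .head(1)
        .reset_index(drop=True)
    )


def upsample_to_max(episodes: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Resample every player up to the season's maximum episode count.

    Within each season, with ``M_s`` the largest number of episodes any player
    has in that season, each player's episodes are augmented by resampling
    with replacement until the player holds exactly ``M_s``; all original
    episodes are always retained. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    pieces = []
    for season in sorted(episodes["season"].unique()):
        sgrp = episodes[episodes["season"] == season]
        m_s = int(sgrp.groupby("player_id").size().max())
        for _, pgrp in sgrp.groupby("player_id", sort=True):
            pieces.append(pgrp)
            deficit = m_s - len(pgrp)
            if deficit > 0:
                pick = rng.integers(0, len(pgrp), size=deficit)
                pieces.append(pgrp.iloc[pick])
    return pd.concat(pieces, ignore_index=True)


def round_robin_split(episodes: pd.DataFrame, k: int = 4, seed: int = 0) -> pd.DataFrame:
    """Assign players to k folds, stratified by playing position.

    Within each position players are shuffled (seeded) and dealt cyclically,
    so per-position fold sizes differ by at most one and identical seeds give
    identical assignments. Returns a frame: player_id, position, fold (1..k).
    """
    rng = np.random.default_rng(seed)
    # one position per player: the position of their most recent episode
    pos = (
        episodes.sort_values("rtp_date")
        .groupby("player_id", sort=True)["position"]
        .last()
    )
    rows = []
    for position in sorted(pos.unique()):
        players = sorted(pos.index[pos == position])
        if len(players) < k:
            raise ValueError(
                f"position {position!r} has {len(players)} players, fewer than k={k}"
            )
        players = list(np.array(players)[rng.permutation(len(players))])
        for i, player in enumerate(players):
            rows.append((player, position, i % k + 1))
    return pd.DataFrame(rows, columns=["player_id", "position", "fold"])


def round_robin_curves(
    episodes: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    degree: int = DEFAULT_DEGREE,
    window: int = DEFAULT_WINDOW,
) -> tuple[pd.DataFrame, dict[str, HazardCurve]]:
    """Leave-one-fold-out hazard curves.

    For each fold, the pipeline is fitted on the complementary (k-1)/k of
    players; the k curves are returned for comparison with the main analysis.
    """
    assignment = round_robin_split(episodes, k=k, seed=seed)
    fold_of = assignment.set_index("player_id")["fold"]
    curves: dict[str, HazardCurve] = {}
    for fold in range(1, k + 1):
        keep = episodes["player_id"].map(fold_of) != fold
        curves[f"fold_{fold}"] = pipeline_hazard(
            episodes[keep], degree=degree, window=window, stratum=f"fold_{fold}"
        )
    return assignment, curves
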