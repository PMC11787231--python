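import datetime as dt

import numpy as np
import pandas as pd
import pytest

from rtphazard import SimulationConfig, default_calendar


def make_record(player, position, injury, time_loss, contact, season="2014/15"):
    injury = dt.date.fromisoformat(injury)
    return {
        "player_id": player,
        "position": position,
        "season": season,
        "injury_date": injury,
        "rtp_date": injury + dt.timedelta(days=time_loss),
        "contact": contact,
        "time_loss_days": time_loss,
    }


@pytest.fixture
def calendar():
    return default_calendar()


@pytest.fixture
def toy_records():
    """Six injuries across two players, enumerated by hand.

    Each player: an index injury followed 30 days after RTP by a non-contact
    injury (observed event), which is followed 10 days after its RTP by a
    contact injury (contact censor), whose own episode runs uninterrupted to
    the 2014/15 last match (season-end censor). So the six records chain into
    exactly 2 events, 2 contact censors, 2 season-end censors.
    """
    rows = [
        # P1: rtp 2014-09-06, next non-contact injury 30 d later
        make_record("P1", "defender", "2014-09-01", 5, contact=False),
        # subsequent injury (event) and index of the next episode; rtp 2014-10-16
        make_record("P1", "defender", "2014-10-06", 10, contact=False),
        # contact injury 10 d after rtp; its own episode -> season end
        make_record("P1", "defender", "2014-10-26", 2, contact=True),
        # P2: rtp 2014-08-18, next non-contact injury 30 d later
        make_record("P2", "forward", "2014-08-15", 3, contact=False),
        # event + index; severe time loss; rtp 2014-10-17
        make_record("P2", "forward", "2014-09-17", 30, contact=False),
        # contact injury 10 d after rtp; episode -> season end
        make_record("P2", "forward", "2014-10-27", 4, contact=True),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_config():
    return SimulationConfig(n_players=30, rng_seed=123)


@pytest.fixture(scope="session")
def recovery_episodes():
    """Episodes from the reference exponential-decay recovery simulation."""
    from rtphazard import build_episodes, exp_decay_recovery_config, simulate_cohort

    cfg = exp_decay_recovery_config(1)
    return build_episodes(simulate_cohort(cfg), cfg.season_calendar)


def brute_force_km(times, events):
    """Independent product-limit recomputation by direct enumeration.

    For every distinct observed time, count at-risk and event episodes from
    scratch and accumulate the product term by term.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    distinct = sorted(set(times))
    s = 1.0
    out = {}
    for tj in distinct:
        n_j = int((times >= tj).sum())
        d_j = int(((times == tj) & events).sum())
        if n_j > 0:
            s *= 1.0 - d_j / n_j
        out[tj] = s
    return out


def random_episode_table(rng, n_max=25):
    n = rng.integers(1, n_max + 1)
    times = rng.integers(1, 40, size=n)
    events = rng.random(n) < 0.6
    if not events.any():
        events[rng.integers(0, n)] = True
    return pd.DataFrame({"time_days": times, "event": events})
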