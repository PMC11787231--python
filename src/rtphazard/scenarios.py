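"""Canonical simulation scenarios.

Three kinds of study: the *reference cohort* emulates a real four-season
league injury register (player frailty, contact injuries, realistic volume);
the *recovery* scenarios switch frailty and contact censoring off so that the
generating hazard is exactly the population hazard and the pipeline's output
can be compared against closed-form truth; the *delayed-peak* scenario builds
a severity-dependent ground truth for testing stratum discrimination.

Frailty is deliberately absent from the recovery scenarios: gamma frailty
size-biases which players contribute episodes and selects low-frailty players
into late risk sets, so the marginal hazard would no longer equal the stated
curve and "recovery" would have no exact target.
"""

from __future__ import annotations

import datetime as dt

from .synthetic import SEVERITIES, ExcessParams, Season, SimulationConfig

__all__ = [
    "reference_cohort_config",
    "exp_decay_recovery_config",
    "constant_hazard_config",
    "delayed_peak_config",
]


def reference_cohort_config(seed: int, n_players: int = 800) -> SimulationConfig:
    """League-scale injury register: gamma frailty, 35% contact injuries.

    With the default per-day baseline of 0.005 this yields roughly 4500-5000
    injuries and ~650 multiply-injured players over the four seasons, with
    about a fifth of episodes censored by a season end.
    """
    return SimulationConfig(rng_seed=seed, n_players=n_players)


def exp_decay_recovery_config(seed: int, n_players: int = 20000) -> SimulationConfig:
    """Exponentially decaying excess with known truth: h(t) = 0.005*(1 + 2^(-t/25)).

    No frailty, no contact injuries; the four-season calendar is kept, so the
    small dilution from summer-break censoring is part of what the pipeline
    must absorb. The large default cohort keeps the Monte-Carlo spread of the
    edge-sensitive day-1 hazard small.
    """
    return SimulationConfig(
        rng_seed=seed,
        n_players=n_players,
        frailty_shape=None,
        baseline_hazard=0.005,
        contact_prob=0.0,
        excess_params={sev: ExcessParams("exp_decay", 1.0, 25.0) for sev in SEVERITIES},
    )


def constant_hazard_config(
    seed: int, n_players: int = 600, baseline: float = 0.01
) -> SimulationConfig:
    """Time-constant hazard (zero excess) over one long uninterrupted season.

    Used to check that the pipeline recovers a flat curve at the right level
    and reports no excess half-time. 600 players over six years give roughly
    10,000 episodes.
    """
    calendar = [Season("long", dt.date(2015, 1, 1), dt.date(2021, 1, 1))]
    return SimulationConfig(
        rng_seed=seed,
        n_players=n_players,
        season_calendar=calendar,
        frailty_shape=None,
        baseline_hazard=baseline,
        contact_prob=0.0,
        excess_params={sev: ExcessParams("exp_decay", 0.0, 25.0) for sev in SEVERITIES},
    )


def delayed_peak_config(seed: int, n_players: int = 10000) -> SimulationConfig:
    """Severity-dependent shapes: severe index injuries ramp to a delayed peak.

    Severe uses the delayed-peak family (peak delay 10 days), every other
    severity the immediate exponential decay, so the fitted severe stratum
    must attain its maximum strictly later than the minimal stratum.
    """
    excess = {sev: ExcessParams("exp_decay", 1.0, 25.0) for sev in SEVERITIES}
    excess["severe"] = ExcessParams("delayed_peak", 1.0, 25.0, peak_delay=10.0)
    return SimulationConfig(
        rng_seed=seed,
        n_players=n_players,
        frailty_shape=None,
        baseline_hazard=0.005,
        contact_prob=0.0,
        excess_params=excess,
    )
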