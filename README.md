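# rtphazard

Continuous-time hazard curves for non-contact injury after return-to-play
(RTP) in professional football.

When a player returns from an injury, the risk of the next injury is elevated
and decays over the following weeks. Estimating that risk trajectory — the
hazard curve — at daily resolution is hard because single days contain few
events, making discrete hazard estimates hopelessly volatile. This package
implements the register-study pipeline that solves this with time-to-event
analysis, and a synthetic cohort generator with known ground truth so every
stage can be validated end to end. It is aimed at sports-injury
epidemiologists and methodologists working with time-to-event data on
recurrent injuries.

## Method

1. **Episodes.** Each injury on a player's record is the *index injury* of one
   episode starting at its RTP date. The episode ends with the player's next
   injury if it is non-contact and in the same season (observed event);
   otherwise it is censored at the next contact injury or at the season's
   last-match date. Index-injury severity follows the time-loss concept:
   minimal 1–3, mild 4–7, moderate 8–28, severe > 28 days.
2. **Survival.** The Kaplan–Meier product-limit estimator at daily
   granularity, Ŝ(t_j) = Π_{t_i ≤ t_j} (1 − d_i/n_i), with Greenwood
   variance and complementary-log-log 95% bands, and the median survival time
   by linear interpolation on the unit-day grid:
   T = m + (Ŝ(t_m) − 0.5)/(Ŝ(t_m) − Ŝ(t_{m+1})).
3. **Hazard retrieval.** The cumulative hazard Ĥ(t_j) = −ln Ŝ(t_j) is a
   smooth accumulation even when daily hazards are noisy. A tenth-degree
   polynomial is least-squares fitted to Ĥ over the first 100 days after RTP
   and the continuous hazard is its rate of change on the day grid,
   h(day) = Ĥ_pred(day) − Ĥ_pred(day − 1) — overall and stratified by
   index-injury severity or playing position.
4. **Robustness.** A baseline comparator re-clocked to start 100 days after
   RTP, up-/down-sampling against the over-representation of frequently
   injured players, and leave-one-quarter-out round-robin splitting at the
   player level.

The synthetic generator simulates players day by day: gamma-frailty-scaled
baseline hazard before the first injury, then a post-RTP excess hazard
h(t) = λ₀(1 + e·2^(−t/τ)) (or a delayed-peak variant) that decays back to
baseline, severity-dependent rehabilitation times, contact flags, and a
four-season calendar with summer breaks.

## Worked example

The numbered scripts under `analysis/` run the whole study on the synthetic
reference cohort and write tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
simulated 4626 injuries for 748 injured players (674 injured more than once)
contact share: 34.6%

$ python analysis/02_build_episodes.py
4519 episodes: 1769 observed events, 2750 censored
  censored at season_end: 1825 (40.4%)
  censored at contact_injury: 925 (20.5%)

$ python analysis/03_fit_hazard_curve.py
median survival: 145.4 days after RTP
hazard at day 1: 0.00834/day; late plateau (days 60-100): 0.00417/day; ratio 2.00
excess half-time: 27.0 days
```

The fitted curve starts at twice its late plateau and sheds half of its
excess within about four weeks — the generating truth built into the cohort.
`04_stratified_curves.py` shows the severity and position strata (severe
index injuries peak later than minimal ones), `05_ancillary_analyses.py` the
baseline comparator (first-month mean 0.00362/day versus 0.00714/day on the
main curve) and the resampling/round-robin checks, and
`06_parameter_recovery.py` the validation against the three known generating
hazards.

The same pipeline is scriptable via the `rtp-hazard` CLI
(`simulate`, `build-episodes`, `fit`, `ancillary`, `report`), each stage
reading and writing plain CSV.

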