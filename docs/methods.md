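# Methods

## Estimand and pipeline

The quantity of interest is the per-day hazard of a non-contact time-loss
injury as a function of days since return-to-play (RTP), over the first 100
days. Direct daily hazard estimates d_j/n_j are unusable at this resolution —
most days hold a handful of events — so the pipeline goes through the
cumulative hazard:

1. Kaplan–Meier product-limit fit over episodes (day granularity),
2. cumulative hazard Ĥ(t_j) = −ln Ŝ(t_j),
3. least-squares polynomial (degree 10) of Ĥ against day over days 0–100,
4. continuous hazard as the unit-day rate of change of the predictions,
   h(day) = Ĥ_pred(day) − Ĥ_pred(day−1), day = 1..100.

The first difference (rather than the analytic derivative of the polynomial)
is used so that the daily hazards telescope exactly to the predicted
cumulative-hazard increment; on the unit-day grid it equals the analytic
derivative at the interval midpoint.

## Episode construction and censoring

Episodes are chained greedily in date order within each player: every injury
is the index injury of one episode and may simultaneously be the subsequent
injury of the previous one. An episode is an observed event only when the
next injury is non-contact *and* occurs in the same season as the RTP; it is
censored at the next injury's date when that injury is contact-related, and
at the season's last-match date otherwise (including when the next injury
falls in a later season — summer exposure and the recording of minor
injuries differ from in-season conditions, so intervals are not carried
across the break). Both contact and non-contact injuries are eligible as
index injuries.

Conventions where the data model is coarser than reality:

- A subsequent injury recorded on the RTP date itself is coded as day 1; the
  daily metric cannot represent sub-day intervals and dropping real events
  would bias the hazard downward.
- An RTP during the summer break (or on a last-match date) is exposed in the
  following season, with the days-since-RTP clock still starting at the
  actual RTP date. An RTP at or after the final season's last match has no
  remaining exposure; the episode is dropped with a warning.
- Playing position is taken from the record of the subsequent injury (the
  outcome); for censored episodes it falls back to the player's most recent
  recorded position.
- At tied days, events are processed before censorings (standard product-limit
  convention).

## Survival estimation

The Kaplan–Meier estimator, Greenwood variance
Var[Ŝ(t)] = Ŝ(t)² Σ d_i/(n_i(n_i−d_i)), and confidence bands on the
log(−log S) scale (which respect [0, 1]; the band collapses to the point
estimate where Ŝ is exactly 0 or 1) are implemented from scratch — their
exactness is what the smoothing stage rests on — and cross-checked in the
test suite against brute-force enumeration and the lifelines reference
implementation to 1e-12. Points where Ŝ has reached 0 are dropped from the
cumulative hazard with a warning. The median survival time is the linear
interpolation T = m + (Ŝ(m) − 0.5)/(Ŝ(m) − Ŝ(m+1)) on the unit-day grid,
with m the last day at which Ŝ is still above 0.5; it is undefined (None)
when Ŝ never falls to 0.5.

## Smoothing choices

- **Response grid.** By default the polynomial is fitted to one point per
  integer day 0..100 carrying the right-continuous step value of Ĥ, so all
  days weigh equally and the high-degree fit is stable; fitting only the
  observed step-change days is available as an option (`grid="event"`).
- **Conditioning.** Raw powers of day 100 at degree 10 would ruin the normal
  equations; the abscissa is affinely mapped onto [−1, 1] (numpy's
  `Polynomial.fit` domain mapping) before solving. Predictions are identical
  to a fit on any other affine rescaling of time.
- **Negative values.** An unconstrained polynomial can produce locally
  negative hazards; they are flagged on the curve object and clamped to zero
  only in plots.
- **Strata.** A stratum needs at least degree+1 distinct event days inside
  the window; sparser strata are skipped with a warning rather than failing
  the run.

## Summary statistics of a fitted curve

The *plateau* is the mean fitted hazard over the last 40% of the window
(days 60–100 by default); the *peak* is the maximum before the plateau
starts. The *excess half-time* is the first day at or after the peak where
the fitted hazard has descended halfway from peak to plateau. Because a
polynomial fitted to noisy but truly flat data always wiggles, a peak within
25% of the plateau (`min_peak_ratio = 1.25`) is treated as no excess: fitted
flat-hazard curves stay below ~1.12 peak-to-plateau at the sample sizes used
here, while a genuine two-fold excess sits near 1.8. Note that with a 25-day
decay half-time, the 60–100-day plateau window still contains ~11% residual
excess; measured against that plateau, the half-crossing of the exact curve
λ₀(1 + 2^(−t/25)) lands at day 22, not 25.

## Synthetic cohort generator

Time is discrete at the day level. Each player carries a mean-1 gamma frailty
(shape 2.0 by default; `None` disables it) multiplying all hazards. Before
the first injury a player is injured with per-day probability
frailty·λ₀; after each RTP with probability frailty·h(t), where t counts
calendar days since the RTP and h follows the excess family of the
*previous* injury's severity:

- `exp_decay`: h(t) = λ₀(1 + e·2^(−t/τ)) — maximal at RTP, halving every τ
  days (defaults e = 1, τ = 25 d);
- `delayed_peak`: h(t) = λ₀(1 + e·(t/d)·exp(1 − t/d)·2^(−t/τ)) — starts at
  baseline, ramps to a peak after roughly d days, then decays.

Injuries draw a contact flag (35%), a severity category (38.9 / 20.2 / 24.5 /
16.4% for minimal/mild/moderate/severe), and a time-loss duration uniform on
the category's day range (severe: 29–180 days, upper bound configurable,
since only a lower bound is epidemiologically defined). Exposure resumes the
day after the RTP date, so the days-since-RTP clock starts at 1 on the daily
grid; no injuries occur during summer breaks, but calendar time keeps
running. The default calendar is four seasons with 1 August starts and
last matches on 23 May 2015, 14 May 2016, 20 May 2017 and 12 May 2018.

With the default per-day baseline λ₀ = 0.005 the reference cohort of 800
players produces roughly 4600–4800 injuries, ~670 multiply-injured players,
~35% contact injuries, and about a fifth of episodes crossing a season end —
the volume and censoring mix of a four-season top-league register.

**What the generator does not emulate:** match schedules, minutes played and
exposure hours (all days in season are equally exposed); injury diagnoses,
locations and recurrence matching; transfers in/out of the league;
non-uniform within-category time-loss distributions. Passing recovery tests
therefore shows that the pipeline retrieves the generating hazard under an
idealized exposure process, not that real-league estimates are unbiased with
respect to exposure variation.

## Validation scenarios and problem sizes

- **Constant hazard** (λ₀ = 0.01/day, zero excess, one uninterrupted
  six-year season, no contact injuries, no frailty; 600 players → ~10,000
  episodes): the fitted curve's mean over days 5–95 must match λ₀ within
  3 Monte-Carlo standard errors and no excess half-time may be reported.
- **Exponential-decay recovery** (λ₀ = 0.005/day, e = 1, τ = 25 d, four
  seasons, no contact, no frailty; 20,000 players → ~116,000 episodes): the
  fitted day-1 hazard must be 1.6–2.4 times the plateau and the excess
  half-time 15–35 days in every seed. The day-1 value of a degree-10
  polynomial sits at the fit boundary and is by far the noisiest point of
  the curve, which is why this scenario uses a large cohort: its Monte-Carlo
  spread at a few thousand players is wider than the scientific bands being
  asserted.
- **Delayed peak** (severe stratum `delayed_peak` with d = 10 d, others
  `exp_decay`; 10,000 players): the fitted severe stratum must attain its
  maximum strictly later than the minimal stratum.

Frailty is deliberately off in all three: gamma frailty size-biases which
players contribute episodes and selects low-frailty players into late risk
sets, so the marginal hazard would no longer equal the stated generating
curve and recovery would have no exact target. The reference cohort keeps
frailty on; its over-dispersion of per-player injury counts is asserted
separately.

## Known limitations

- The degree-10 polynomial is unconstrained: it can go locally negative and
  is least reliable at the window edges (day 1 and day 100); the baseline
  comparator, with fewer and longer episodes, visibly over-fits, as the
  round-robin analysis is designed to expose.
- Censoring is treated as non-informative; under frailty this is only an
  approximation (frequently injured players are censored by contact injuries
  at a higher rate).
- Calendar censoring at season end means late-starting episodes contribute
  little follow-up; episodes beginning in the summer break dilute the early
  curve by a few percent because their first exposed day comes after the
  clock has started.
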