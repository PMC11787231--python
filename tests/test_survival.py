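import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtphazard import (
    cumulative_hazard,
    daily_grid,
    greenwood_band,
    km_fit,
    median_survival,
)
from tests.conftest import brute_force_km, random_episode_table


def table(times, events):
    return pd.DataFrame({"time_days": times, "event": events})


class TestKmFit:
    def test_single_event_steps_to_zero(self):
        curve = km_fit(table([5], [True]))
        assert curve.survival_at([4, 5]) == pytest.approx([1.0, 0.0])

    def test_hand_computed_product_limit(self):
        # event d1, censor d2, event d3, censor d10
        curve = km_fit(table([1, 2, 3, 10], [True, False, True, False]))
        assert curve.survival_at(1) == pytest.approx(0.75, abs=1e-15)
        assert curve.survival_at(3) == pytest.approx(0.375, abs=1e-15)
        assert list(curve.n_at_risk) == [4, 3, 2, 1]

    def test_no_censoring_reduces_to_ecdf(self):
        rng = np.random.default_rng(5)
        times = rng.integers(1, 30, size=40)
        curve = km_fit(table(times, [True] * 40))
        grid = np.arange(0, 31)
        ecdf = np.array([(times <= t).mean() for t in grid])
        assert curve.survival_at(grid) == pytest.approx(1 - ecdf, abs=1e-12)

    def test_empty_rejected_and_all_censored_warns(self):
        with pytest.raises(ValueError):
            km_fit(table([], []))
        with pytest.warns(UserWarning, match="censored"):
            curve = km_fit(table([3, 4], [False, False]))
        assert curve.all_censored
        assert curve.survival == pytest.approx([1.0, 1.0])

    def test_matches_brute_force_and_lifelines_oracles(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2024)
        for _ in range(50):
            eps = random_episode_table(rng)
            curve = km_fit(eps)
            brute = brute_force_km(eps["time_days"], eps["event"])
            for tj, s in brute.items():
                assert curve.survival_at(tj) == pytest.approx(s, abs=1e-12)
            kmf = lifelines.KaplanMeierFitter().fit(eps["time_days"], eps["event"])
            ref = kmf.survival_function_["KM_estimate"]
            for tj in curve.times:
                assert curve.survival_at(tj) == pytest.approx(ref.loc[tj], abs=1e-12)


class TestGreenwood:
    def test_hand_computed_variance(self):
        curve = km_fit(table([1, 5], [True, False]))
        # S=0.5, Greenwood var = 0.25 * 1/(2*1) = 0.125
        assert curve.greenwood_var[0] == pytest.approx(0.125, abs=1e-15)

    def test_no_events_band_is_unit(self):
        with pytest.warns(UserWarning):
            curve = km_fit(table([2, 3], [False, False]))
        assert curve.ci_lower == pytest.approx([1.0, 1.0])
        assert curve.ci_upper == pytest.approx([1.0, 1.0])

    def test_band_collapses_as_level_vanishes(self):
        curve = km_fit(table([1, 2, 3, 10], [True, False, True, False]))
        tight = greenwood_band(curve, level=1e-12)
        assert tight.ci_lower == pytest.approx(tight.survival, abs=1e-6)
        assert tight.ci_upper == pytest.approx(tight.survival, abs=1e-6)

    def test_level_outside_unit_interval_rejected(self):
        curve = km_fit(table([1], [True]))
        for bad in (0.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                greenwood_band(curve, level=bad)


class TestCumulativeHazard:
    def test_closed_form_values(self):
        curve = km_fit(table([1, 2, 3, 10], [True, False, True, False]))
        ch = cumulative_hazard(curve)
        assert ch.at(1) == pytest.approx(np.log(4 / 3), abs=1e-15)
        assert ch.at(3) == pytest.approx(-np.log(0.375), abs=1e-15)
        assert ch.at(3) == pytest.approx(0.98082925301172619, abs=1e-12)

    def test_round_trip_is_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            eps = random_episode_table(rng)
            curve = km_fit(eps)
            ch = cumulative_hazard(curve)
            keep = curve.survival > 0
            assert np.exp(-ch.cum_hazard) == pytest.approx(
                curve.survival[keep], abs=1e-12
            )

    def test_s_zero_points_dropped_with_warning(self):
        curve = km_fit(table([2], [True]))
        with pytest.warns(UserWarning, match="S=0"):
            ch = cumulative_hazard(curve)
        assert ch.times.size == 0


class TestMedianSurvival:
    def test_interpolated_value(self):
        # S(10)=0.6 (2/5 events at day 10), S(11)=0.4 -> T = 10.5
        curve = km_fit(table([10, 10, 11, 20, 20], [True, True, True, False, False]))
        assert curve.survival_at(10) == pytest.approx(0.6)
        assert curve.survival_at(11) == pytest.approx(0.4)
        assert median_survival(curve) == pytest.approx(10.5, abs=1e-12)

    def test_unit_drop_gives_midpoint(self):
        curve = km_fit(table([7], [True]))
        assert median_survival(curve) == pytest.approx(6.5, abs=1e-12)

    def test_none_when_s_stays_above_half(self):
        with pytest.warns(UserWarning):
            curve = km_fit(table([3, 4], [False, False]))
        assert median_survival(curve) is None

    def test_no_censoring_median_between_middle_order_stats(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            times = rng.integers(1, 50, size=2 * rng.integers(2, 15))
            curve = km_fit(table(times, [True] * len(times)))
            med = median_survival(curve)
            srt = np.sort(times)
            lo, hi = srt[len(srt) // 2 - 1], srt[len(srt) // 2]
            assert lo - 1 <= med <= hi


@settings(deadline=None, max_examples=80, derandomize=True)
@given(
    times=st.lists(st.integers(min_value=1, max_value=60), min_size=1, max_size=40),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_curve_invariants_hold_for_any_input(times, seed):
    """S and H monotone, S in [0,1], risk set telescopes, bands bracket S."""
    rng = np.random.default_rng(seed)
    events = rng.random(len(times)) < 0.5
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = km_fit(table(times, events))
        ch = cumulative_hazard(curve)
    assert np.all(np.diff(curve.survival) <= 1e-15)
    assert np.all((curve.survival >= 0) & (curve.survival <= 1))
    assert np.all(np.diff(ch.cum_hazard) >= -1e-15)
    n, d, c = curve.n_at_risk, curve.n_events, curve.n_censored
    assert np.all(n[1:] == n[:-1] - d[:-1] - c[:-1])
    assert np.all(curve.ci_lower <= curve.survival + 1e-12)
    assert np.all(curve.ci_upper >= curve.survival - 1e-12)


def test_daily_grid_has_one_row_per_day():
    curve = km_fit(table([1, 2, 3, 10], [True, False, True, False]))
    grid = daily_grid(curve, max_day=15)
    assert list(grid["day"]) == list(range(16))
    assert grid["n_events"].sum() == 2
    assert grid.loc[5, "S"] == pytest.approx(0.375)
    assert grid.loc[0, "S"] == 1.0
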