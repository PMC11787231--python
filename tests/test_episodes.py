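import datetime as dt
import logging

import pandas as pd
import pytest

from rtphazard import (
    SimulationConfig,
    build_episodes,
    categorize_severity,
    constant_hazard_config,
    episode_summary,
    read_episodes_csv,
    simulate_cohort,
    write_episodes_csv,
)
from tests.conftest import make_record


@pytest.mark.parametrize(
    "days,expected",
    [
        (1, "minimal"),
        (3, "minimal"),
        (4, "mild"),
        (7, "mild"),
        (8, "moderate"),
        (28, "moderate"),
        (29, "severe"),
        (200, "severe"),
    ],
)
def test_severity_category_bounds(days, expected):
    assert categorize_severity(days) == expected


def test_severity_rejects_nonpositive():
    with pytest.raises(ValueError):
        categorize_severity(0)


class TestBuildEpisodes:
    def test_toy_table_exact_classification(self, toy_records, calendar):
        """Hand-enumerated toy: 2 events, 2 contact censors, 2 season-end censors."""
        eps = build_episodes(toy_records, calendar)
        assert len(eps) == 6
        s = episode_summary(eps)
        assert s["n_observed"] == 2
        assert s["censor_reasons"] == {"season_end": 2, "contact_injury": 2}
        events = eps[eps["event"]]
        assert sorted(events["time_days"]) == [30, 30]
        contact = eps[eps["censor_reason"] == "contact_injury"]
        assert sorted(contact["time_days"]) == [10, 10]
        # index severities follow the index injury's time loss
        p2 = eps[eps["player_id"] == "P2"].sort_values("rtp_date")
        assert list(p2["index_severity"]) == ["minimal", "severe", "mild"]

    def test_season_end_censor_lands_on_last_match(self, toy_records, calendar):
        eps = build_episodes(toy_records, calendar)
        se = eps[eps["censor_reason"] == "season_end"]
        last = {s.label: s.last_match for s in calendar}
        for row in se.itertuples():
            assert row.rtp_date + dt.timedelta(days=row.time_days) == last[row.season]

    def test_position_taken_from_outcome_record(self, calendar):
        rows = [
            make_record("P1", "midfielder", "2014-09-01", 5, contact=False),
            make_record("P1", "forward", "2014-10-06", 3, contact=False),
        ]
        eps = build_episodes(pd.DataFrame(rows), calendar).sort_values("rtp_date")
        # event episode: position of the subsequent-injury record; censored
        # episode: fallback to the most recent recorded position
        assert list(eps["position"]) == ["forward", "forward"]

    def test_next_injury_in_later_season_censors_at_season_end(self, calendar):
        rows = [
            make_record("P1", "defender", "2014-09-01", 5, contact=False),
            make_record("P1", "defender", "2015-09-10", 5, contact=False, season="2015/16"),
        ]
        eps = build_episodes(pd.DataFrame(rows), calendar).sort_values("rtp_date")
        first = eps.iloc[0]
        assert not first["event"]
        assert first["censor_reason"] == "season_end"
        assert first["rtp_date"] + dt.timedelta(days=int(first["time_days"])) == dt.date(2015, 5, 23)

    def test_injury_on_rtp_day_coded_as_day_one(self, calendar):
        rows = [
            make_record("P1", "defender", "2014-09-01", 5, contact=False),
            make_record("P1", "defender", "2014-09-06", 7, contact=False),
        ]
        eps = build_episodes(pd.DataFrame(rows), calendar).sort_values("rtp_date")
        assert eps.iloc[0]["event"]
        assert eps.iloc[0]["time_days"] == 1

    def test_rtp_in_summer_break_rolls_to_next_season(self, calendar):
        # severe injury late in 2014/15; rtp 2015-06-29 falls in the break
        rows = [make_record("P1", "defender", "2015-04-30", 60, contact=False)]
        eps = build_episodes(pd.DataFrame(rows), calendar)
        assert len(eps) == 1
        assert eps.iloc[0]["season"] == "2015/16"
        assert eps.iloc[0]["rtp_date"] == dt.date(2015, 6, 29)

    def test_rtp_after_final_season_dropped_with_warning(self, calendar, caplog):
        rows = [make_record("P1", "defender", "2018-05-10", 30, contact=False, season="2017/18")]
        with caplog.at_level(logging.WARNING):
            eps = build_episodes(pd.DataFrame(rows), calendar)
        assert len(eps) == 0
        assert "no remaining season exposure" in caplog.text

    def test_overlapping_records_rejected(self, calendar):
        rows = [
            make_record("P1", "defender", "2014-09-01", 30, contact=False),
            make_record("P1", "defender", "2014-09-10", 3, contact=False),
        ]
        with pytest.raises(ValueError, match="overlaps"):
            build_episodes(pd.DataFrame(rows), calendar)

    def test_episode_count_identity(self):
        """Episodes = injury records minus dropped edge cases."""
        cfg = SimulationConfig(n_players=150, rng_seed=77)
        rec = simulate_cohort(cfg)
        eps = build_episodes(rec, cfg.season_calendar)
        final = cfg.season_calendar[-1].last_match
        dropped = (rec["rtp_date"] >= final).sum()
        assert len(eps) == len(rec) - dropped

    def test_no_event_crosses_season_boundary(self):
        cfg = SimulationConfig(n_players=150, rng_seed=78)
        eps = build_episodes(simulate_cohort(cfg), cfg.season_calendar)
        last = {s.label: s.last_match for s in cfg.season_calendar}
        ev = eps[eps["event"]]
        for row in ev.itertuples():
            assert row.rtp_date + dt.timedelta(days=row.time_days) <= last[row.season]

    def test_single_season_no_contact_censors_equal_last_injuries(self):
        """With one never-ending season and no contact injuries, the censored
        episodes are exactly each player's last injury."""
        cfg = constant_hazard_config(41, n_players=80)
        rec = simulate_cohort(cfg)
        eps = build_episodes(rec, cfg.season_calendar)
        n_players_injured = rec["player_id"].nunique()
        final = cfg.season_calendar[-1].last_match
        n_dropped = (rec["rtp_date"] >= final).sum()
        assert (~eps["event"]).sum() == n_players_injured - n_dropped
        assert set(eps["censor_reason"]) <= {"none", "season_end"}


class TestEpisodeIO:
    def test_round_trip_identical(self, toy_records, calendar, tmp_path):
        eps = build_episodes(toy_records, calendar)
        path = tmp_path / "eps.csv"
        write_episodes_csv(eps, path)
        again = read_episodes_csv(path)
        pd.testing.assert_frame_equal(eps.reset_index(drop=True), again)

    def test_summary_counts(self, toy_records, calendar):
        eps = build_episodes(toy_records, calendar)
        s = episode_summary(eps)
        assert s["n_episodes"] == s["n_observed"] + s["n_censored"] == 6
        assert sum(s["censor_reasons"].values()) == s["n_censored"]

    def test_empty_summary_is_not_an_error(self):
        s = episode_summary(pd.DataFrame(columns=["event", "censor_reason"]))
        assert s["n_episodes"] == 0
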