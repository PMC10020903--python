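"""Episode reconstruction and per-encounter roll-up."""

import datetime as dt

import pandas as pd
import pytest

from alertmon import (
    build_episodes,
    determine_modality,
    documentation_complete,
    outcomes_to_frame,
    rollup_encounters,
    simulate,
    window_index,
)
from alertmon.episodes import AlertInstance, add_months

from .conftest import small_sim_config

RELEVANCE = {"office_visit": "relevant", "lab_visit": "less_relevant"}


def _instance(trigger="chart_open", action="defer", when="2024-01-01T09:00:00Z", dur=10):
    t = pd.Timestamp(when)
    responded = action != "no_response"
    return AlertInstance(
        instance_id="i",
        firing_time=t,
        response_time=t + pd.Timedelta(seconds=dur) if responded else None,
        triggering_condition=trigger,
        canonical_action=action,
        duration_s=dur if responded else None,
        referral_ordered=False,
    )


class TestModality:
    def test_chart_open_is_interruptive(self):
        assert determine_modality([_instance("chart_open")]) == "interruptive"

    def test_passive_display_is_noninterruptive(self):
        assert determine_modality([_instance("noninterruptive_display")]) == "noninterruptive"

    def test_mixed_counts_as_interruptive(self):
        instances = [_instance("noninterruptive_display"), _instance("timer_refire")]
        assert determine_modality(instances) == "interruptive"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            determine_modality([])


class TestBuildEpisodes:
    def test_toy10_episode_count_and_conservation(self, toy10):
        episodes = build_episodes(toy10)
        assert len(episodes) == 9
        assert sum(e.n_firings for e in episodes) == len(toy10.alert_events)

    def test_defer_defer_ack_completes(self, toy10):
        a9 = next(e for e in build_episodes(toy10) if e.alert_id == "A9")
        assert a9.n_firings == 3
        assert a9.completed and a9.deferred_any
        assert a9.final_action == "ack_complete_screening"
        assert a9.complete_time_s == 50
        assert a9.postpone_time_s == 100

    def test_no_response_episode(self, toy10):
        a6 = next(e for e in build_episodes(toy10) if e.alert_id == "A6")
        assert a6.final_action == "no_response"
        assert not a6.completed and a6.n_firings == 1

    def test_defer_only_episode_not_completed(self, toy10):
        a4 = next(e for e in build_episodes(toy10) if e.alert_id == "A4")
        assert a4.final_action == "defer"
        assert not a4.completed and a4.deferred_any

    def test_instances_time_ordered_with_id_tiebreak(self, toy10):
        d = toy10.copy()
        # force a firing-time tie inside episode A9: order must fall back to ids
        t = d.alert_events.loc[d.alert_events["alert_instance_id"] == "A9-I1", "firing_time"].iloc[0]
        d.alert_events.loc[d.alert_events["alert_instance_id"] == "A9-I2", "firing_time"] = t
        a9 = next(e for e in build_episodes(d) if e.alert_id == "A9")
        assert [i.instance_id for i in a9.instances] == ["A9-I1", "A9-I2", "A9-I3"]

    def test_support_episode_completion_is_discussion(self, toy10):
        a7 = next(e for e in build_episodes(toy10) if e.alert_id == "A7")
        assert a7.alert_kind == "support"
        assert a7.completed  # discussed, though not ready to quit
        assert a7.final_action == "discussed_not_ready"


class TestDocumentation:
    def test_all_questions_answered(self):
        rows = [{"flowsheet_name": q, "flowsheet_value": "x"} for q in ("Q1", "Q2", "Q3")]
        assert documentation_complete(rows, ("Q1", "Q2", "Q3"))

    def test_missing_question_fails(self):
        rows = [{"flowsheet_name": q, "flowsheet_value": "x"} for q in ("Q1", "Q2")]
        assert not documentation_complete(rows, ("Q1", "Q2", "Q3"))

    def test_empty_answer_does_not_count(self):
        rows = [
            {"flowsheet_name": "Q1", "flowsheet_value": "x"},
            {"flowsheet_name": "Q2", "flowsheet_value": "x"},
            {"flowsheet_name": "Q3", "flowsheet_value": ""},
        ]
        assert not documentation_complete(rows, ("Q1", "Q2", "Q3"))


class TestWindows:
    def test_calendar_month_arithmetic_clamps(self):
        assert add_months(dt.date(2024, 1, 31), 1) == dt.date(2024, 2, 29)
        assert add_months(dt.date(2023, 11, 30), 3) == dt.date(2024, 2, 29)

    @pytest.mark.parametrize(
        "when,expected",
        [
            ("2024-01-01T00:00:00Z", 0),
            ("2024-03-31T23:59:59Z", 0),
            ("2024-04-01T00:00:00Z", 1),
            ("2024-12-31T23:59:59Z", 3),
            ("2025-01-01T00:00:00Z", None),  # at 12 months: out of horizon
            ("2023-12-31T23:59:59Z", None),  # before go-live
        ],
    )
    def test_window_index_half_open(self, when, expected):
        assert window_index(pd.Timestamp(when), dt.date(2024, 1, 1)) == expected


class TestRollup:
    def test_toy10_outcomes(self, toy10_result):
        frame = toy10_result.frame
        assert len(frame) == 8  # encounters with >= 1 alert
        assert int(frame["screening_fired"].sum()) == 7
        assert int(frame["screening_ack_completed"].sum()) == 4
        assert int(frame["screening_documented"].sum()) == 1
        assert int(frame["support_fired"].sum()) == 2
        assert int(frame["support_discussed"].sum()) == 2
        assert int(frame["support_ready_to_quit"].sum()) == 1
        assert int(frame["support_referral_ordered"].sum()) == 1
        assert int(frame["support_no_postpone"].sum()) == 1

    def test_acknowledged_but_undocumented_gap(self, toy10_result):
        # E02 acknowledged completion with no flowsheet rows at all
        row = toy10_result.frame.set_index("encounter_id").loc["E02"]
        assert row["screening_ack_completed"] and not row["screening_documented"]

    def test_defer_only_encounter_flags(self, toy10_result):
        row = toy10_result.frame.set_index("encounter_id").loc["E03"]
        assert row["screening_deferred_any"] and not row["screening_ack_completed"]

    def test_unmapped_encounter_type_raises(self, toy10):
        episodes = build_episodes(toy10)
        with pytest.raises(KeyError, match="lab_visit"):
            rollup_encounters(episodes, toy10, {"office_visit": "relevant"})

    def test_conservation_against_event_table(self, sim_medium):
        _, dataset, _ = sim_medium
        episodes = build_episodes(dataset)
        for kind in ("screening", "support"):
            n_events = int((dataset.alert_events["alert_name"] == kind).sum())
            assert sum(e.n_firings for e in episodes if e.alert_kind == kind) == n_events
        outcomes = rollup_encounters(episodes, dataset, RELEVANCE | {
            "initial_consultation": "relevant", "radiation_treatment_visit": "less_relevant"})
        frame = outcomes_to_frame(outcomes)
        fired_encounters = dataset.alert_events.loc[
            dataset.alert_events["alert_name"] == "screening", "encounter_id"
        ].nunique()
        assert int(frame["screening_fired"].sum()) == fired_encounters

    def test_rollup_matches_ground_truth_flags(self, sim_medium):
        config, dataset, truth = sim_medium
        episodes = build_episodes(dataset)
        frame = (
            outcomes_to_frame(rollup_encounters(episodes, dataset, config.relevance_map()))
            .set_index("encounter_id")
        )
        ledger = truth.fired("screening").set_index("encounter_id")
        flags = [
            "screening_ack_completed",
            "screening_documented",
            "screening_deferred_any",
            "screening_not_appropriate",
            "support_fired",
            "support_no_postpone",
            "support_discussed",
            "support_ready_to_quit",
            "support_referral_ordered",
        ]
        for flag in flags:
            got = frame.loc[ledger.index, flag].astype(bool)
            want = ledger[flag].astype(bool)
            assert (got == want).all(), flag
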