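"""Metric families: completion rates, trends, firing rate, handling time,
stratification and the two-proportion comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from alertmon import (
    UndefinedRateError,
    completion_rate,
    completion_trend,
    firing_rate,
    handling_time,
    round_half_up,
    simulate,
    stratify_completion,
    two_proportion_test,
)
from alertmon.pipeline import run_pipeline

from .conftest import small_sim_config


@pytest.fixture(scope="module")
def sim_frame(sim_medium):
    config, dataset, _ = sim_medium
    result = run_pipeline(dataset, config.relevance_map())
    return result.frame, result.episodes


class TestCompletionRate:
    def test_toy10_hand_counts(self, toy10_result):
        frame = toy10_result.frame
        ack = completion_rate(frame, "ack")
        assert (ack.numerator, ack.denominator) == (4, 7)
        documented = completion_rate(frame, "documented")
        assert (documented.numerator, documented.denominator) == (1, 7)
        discussion = completion_rate(frame, "discussion")
        assert (discussion.numerator, discussion.denominator) == (2, 2)
        referral = completion_rate(frame, "referral")
        assert (referral.numerator, referral.denominator) == (1, 2)

    def test_zero_completions_gives_zero(self, toy10_result):
        frame = toy10_result.frame.copy()
        frame["screening_ack_completed"] = False
        assert completion_rate(frame, "ack").rate == 0.0

    def test_empty_denominator_raises(self, toy10_result):
        frame = toy10_result.frame
        with pytest.raises(UndefinedRateError):
            completion_rate(frame, "ack", where=frame["clinic_id"] == "NOPE")

    def test_monotone_in_added_completed_encounter(self, toy10_result):
        frame = toy10_result.frame
        before = completion_rate(frame, "ack").rate
        extra = frame.iloc[[0]].copy()
        extra["encounter_id"] = "E-NEW"
        extra["screening_fired"] = True
        extra["screening_ack_completed"] = True
        after = completion_rate(pd.concat([frame, extra], ignore_index=True), "ack").rate
        assert after >= before


class TestTrend:
    def test_toy10_windows(self, toy10_result):
        trend = completion_trend(toy10_result.frame, "ack").to_frame()
        c1 = trend[trend["clinic_id"] == "C1"].set_index("window_index")
        assert c1.loc[0, "numerator"] == 1 and c1.loc[0, "denominator"] == 2  # E01, E05
        assert set(c1.index) == {0, 1, 2, 3}
        pooled = trend[trend["clinic_id"] == "ALL"]
        # pooled numerators/denominators are the clinic sums per window
        clinics = trend[trend["clinic_id"] != "ALL"]
        for window, row in pooled.set_index("window_index").iterrows():
            sub = clinics[clinics["window_index"] == window]
            assert row["numerator"] == sub["numerator"].sum()
            assert row["denominator"] == sub["denominator"].sum()

    def test_window_denominators_sum_to_total(self, sim_frame):
        frame, _ = sim_frame
        trend = completion_trend(frame, "ack").to_frame()
        in_horizon = frame[frame["screening_fired"] & frame["window_index"].notna()]
        pooled = trend[trend["clinic_id"] == "ALL"]
        assert pooled["denominator"].sum() == len(in_horizon)

    def test_constant_probability_gives_stable_windows(self):
        dataset, truth = simulate(small_sim_config(seed=21, n_encounters=8000))
        config = small_sim_config(seed=21, n_encounters=8000)
        result = run_pipeline(dataset, config.relevance_map())
        trend = completion_trend(result.frame, "ack").to_frame()
        pooled = trend[trend["clinic_id"] == "ALL"]
        p = 0.55
        for _, row in pooled.iterrows():
            se = np.sqrt(p * (1 - p) / row["denominator"])
            assert abs(row["rate"] - p) < 3 * se


class TestFiringRate:
    def test_toy10_interruptive_only(self, toy10_result):
        fr = firing_rate(toy10_result.episodes, "screening")
        assert (fr.fired, fr.completed) == (10, 3)
        assert fr.rounded() == 3.3

    def test_toy10_including_noninterruptive(self, toy10_result):
        fr = firing_rate(toy10_result.episodes, "screening", interruptive_only=False)
        assert (fr.fired, fr.completed) == (11, 4)

    def test_support(self, toy10_result):
        fr = firing_rate(toy10_result.episodes, "support")
        assert (fr.fired, fr.completed) == (3, 2)

    def test_all_first_firing_completions_give_one(self):
        dataset, _ = simulate(
            small_sim_config(
                seed=3, n_encounters=300, p_ack_complete=1.0, p_not_appropriate=0.0, p_stop=1.0
            )
        )
        result = run_pipeline(dataset, small_sim_config(seed=3).relevance_map())
        fr = firing_rate(result.episodes, "screening")
        assert fr.rate == 1.0

    def test_zero_completions_undefined(self, toy10_result):
        eps = [e for e in toy10_result.episodes if not e.completed]
        fr = firing_rate(eps, "screening")
        assert fr.undefined and fr.rate is None and fr.rounded() is None

    def test_at_least_one_when_defined(self, sim_frame):
        _, episodes = sim_frame
        for kind in ("screening", "support"):
            fr = firing_rate(episodes, kind)
            if not fr.undefined:
                assert fr.rate >= 1.0


class TestHandlingTime:
    def test_toy10_hand_means(self, toy10_result):
        ht = handling_time(toy10_result.frame, "screening")
        assert ht.n_complete_encounters == 4
        assert ht.mean_complete_s == pytest.approx(125 / 4)  # 40, 15, 20, 50
        assert ht.n_postpone_encounters == 3
        assert ht.mean_postpone_s == pytest.approx(190 / 3)  # 30, 60, 45+55
        support = handling_time(toy10_result.frame, "support")
        assert support.mean_complete_s == pytest.approx(27.5)  # 20, 35
        assert support.mean_postpone_s == pytest.approx(25.0)

    def test_single_completing_instance_equals_duration(self, toy10_result):
        frame = toy10_result.frame
        only_e07 = frame[frame["encounter_id"] == "E07"]
        assert handling_time(only_e07, "screening").mean_complete_s == 20.0

    def test_brute_force_recomputation_on_simulated_data(self, sim_frame):
        """Per-encounter means equal a direct recomputation from instance durations."""
        frame, episodes = sim_frame
        complete, postpone = {}, {}
        for e in episodes:
            if e.alert_kind != "screening":
                continue
            for i in e.instances:
                if i.duration_s is None:
                    continue
                if i.responded:
                    complete[e.encounter_id] = complete.get(e.encounter_id, 0) + i.duration_s
                elif i.deferred:
                    postpone[e.encounter_id] = postpone.get(e.encounter_id, 0) + i.duration_s
        completed_ids = set(frame.loc[frame["screening_ack_completed"], "encounter_id"])
        deferred_ids = set(frame.loc[frame["screening_deferred_any"], "encounter_id"])
        want_complete = np.mean([v for k, v in complete.items() if k in completed_ids])
        want_postpone = np.mean([v for k, v in postpone.items() if k in deferred_ids])
        ht = handling_time(frame, "screening")
        assert ht.mean_complete_s == pytest.approx(want_complete)
        assert ht.mean_postpone_s == pytest.approx(want_postpone)

    def test_instance_aggregation_switch(self, sim_frame):
        frame, episodes = sim_frame
        ht = handling_time(frame, "screening", aggregation="instance", episodes=episodes)
        durations = [
            i.duration_s
            for e in episodes
            if e.alert_kind == "screening" and e.completed
            for i in e.instances
            if i.responded and i.duration_s is not None
        ]
        assert ht.mean_complete_s == pytest.approx(np.mean(durations))


class TestStratification:
    def test_single_stratum_equals_overall(self, toy10_result):
        frame = toy10_result.frame.copy()
        frame["relevance"] = "relevant"
        table = stratify_completion(frame, "ack", ["relevance"])
        overall = completion_rate(frame, "ack")
        assert len(table) == 1
        assert table.iloc[0]["numerator"] == overall.numerator
        assert table.iloc[0]["denominator"] == overall.denominator

    def test_toy10_relevance_split(self, toy10_result):
        table = stratify_completion(toy10_result.frame, "ack", ["relevance"]).set_index("relevance")
        assert table.loc["relevant", "numerator"] == 4
        assert table.loc["relevant", "denominator"] == 6
        assert table.loc["less_relevant", "denominator"] == 1

    def test_strata_partition_totals(self, sim_frame):
        frame, _ = sim_frame
        overall = completion_rate(frame, "ack")
        for keys in (["sex"], ["race"], ["sex", "race"], ["relevance", "clinic_id"]):
            table = stratify_completion(frame, "ack", keys)
            assert table["numerator"].sum() == overall.numerator
            assert table["denominator"].sum() == overall.denominator

    def test_balanced_strata_near_generator_probability(self):
        config = small_sim_config(seed=5, n_encounters=20000)
        dataset, _ = simulate(config)
        frame = run_pipeline(dataset, config.relevance_map()).frame
        table = stratify_completion(frame, "ack", ["sex", "race"])
        p = 0.55
        for _, row in table.iterrows():
            if row["denominator"] < 30:
                continue
            se = np.sqrt(p * (1 - p) / row["denominator"])
            assert abs(row["rate"] - p) < 3 * se

    def test_empty_keys_rejected(self, toy10_result):
        with pytest.raises(ValueError):
            stratify_completion(toy10_result.frame, "ack", [])


class TestTwoProportion:
    def test_equal_proportions_degenerate(self):
        r = two_proportion_test(3, 10, 3, 10)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_all_failures_degenerate_margin(self):
        r = two_proportion_test(0, 10, 0, 7)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_matches_closed_form_identity(self):
        # chi-square on a 2x2 equals N(ad-bc)^2 / (r1 r2 c1 c2)
        x1, n1, x2, n2 = 3, 10, 7, 10
        r = two_proportion_test(x1, n1, x2, n2)
        a, b, c, d = x1, n1 - x1, x2, n2 - x2
        n = n1 + n2
        want = n * (a * d - b * c) ** 2 / (n1 * n2 * (a + c) * (b + d))
        assert r.statistic == pytest.approx(want)
        assert r.p_value == pytest.approx(stats.chi2.sf(want, 1))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            two_proportion_test(11, 10, 1, 10)

    def test_monte_carlo_permutation_matches_exact_enumeration(self):
        """The label-permutation null (margins fixed) is hypergeometric; the
        Monte-Carlo estimate at 1e5 draws must sit within 0.01 of the
        enumerated exact permutation p for the 3/10-vs-7/10 table."""
        x1, n1, x2, n2 = 3, 10, 7, 10
        obs = two_proportion_test(x1, n1, x2, n2).statistic
        # exact: sum hypergeometric pmf over tables with statistic >= observed
        k = np.arange(0, x1 + x2 + 1)
        pmf = stats.hypergeom.pmf(k, n1 + n2, x1 + x2, n1)
        stats_k = np.array(
            [two_proportion_test(int(kk), n1, x1 + x2 - int(kk), n2).statistic for kk in k]
        )
        exact = float(pmf[stats_k >= obs - 1e-12].sum())
        rng = np.random.default_rng(20240101)
        draws = rng.hypergeometric(x1 + x2, n1 + n2 - x1 - x2, n1, size=100_000)
        mc_stats = np.array(
            [two_proportion_test(int(kk), n1, x1 + x2 - int(kk), n2).statistic for kk in k]
        )
        stat_of = dict(zip(k.tolist(), mc_stats.tolist()))
        mc = float(np.mean([stat_of[int(d)] >= obs - 1e-12 for d in draws]))
        assert mc == pytest.approx(exact, abs=0.01)


class TestRounding:
    @pytest.mark.parametrize(
        "value,digits,want",
        [(2.05625, 1, 2.1), (0.345, 2, 0.35), (12.011, 1, 12.0), (2.669, 1, 2.7), (52.5, 0, 53.0)],
    )
    def test_half_up(self, value, digits, want):
        assert round_half_up(value, digits) == want

    @given(st.integers(1, 300), st.integers(0, 300))
    @settings(max_examples=100, deadline=None)
    def test_rates_stay_in_unit_interval(self, den, num):
        num = min(num, den)
        frame = pd.DataFrame(
            {
                "screening_fired": [True] * den,
                "screening_ack_completed": [True] * num + [False] * (den - num),
            }
        )
        r = completion_rate(frame, "ack")
        assert 0.0 <= r.rate <= 1.0
        assert (r.numerator, r.denominator) == (num, den)
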