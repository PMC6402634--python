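"""Analysis suite: balanced performance, sliding windows, TTC, sessions,
circadian profiles, learner stratification, water curve, context pooling."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gonogo import io as gio
from gonogo.analysis import (
    fast_slow_split,
    hourly_profiles,
    performance,
    reward_trials_curve,
    segment_sessions,
    sliding_performance,
    task_context_pooling,
    trials_to_criterion,
)

from conftest import make_records


class TestPerformance:
    def test_all_correct_is_one(self):
        assert performance(["H"] * 5 + ["CR"] * 5) == 1.0

    def test_hits_plus_false_alarms_average_to_half(self):
        assert performance(["H"] * 10 + ["FA"] * 10) == 0.5

    def test_printed_formula_on_6_of_10_and_8_of_10(self):
        outcomes = ["H"] * 6 + ["M"] * 4 + ["CR"] * 8 + ["FA"] * 2
        assert performance(outcomes) == pytest.approx(0.7)

    def test_missing_class_is_undefined(self):
        assert math.isnan(performance(["H", "M", "H"]))
        assert math.isnan(performance([]))

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ValueError):
            performance(["H", "X"])

    @settings(max_examples=200, deadline=None)
    @given(
        h=st.integers(0, 30), m=st.integers(0, 30),
        cr=st.integers(0, 30), fa=st.integers(0, 30),
    )
    def test_matches_brute_force_recount(self, h, m, cr, fa):
        outcomes = ["H"] * h + ["M"] * m + ["CR"] * cr + ["FA"] * fa
        got = performance(outcomes)
        if h + m == 0 or cr + fa == 0:
            assert math.isnan(got)
        else:
            assert got == pytest.approx(0.5 * (h / (h + m) + cr / (cr + fa)))

    @settings(max_examples=100, deadline=None)
    @given(
        acc_p=st.fractions(0, 1), acc_m=st.fractions(0, 1),
        n_p=st.integers(1, 40), n_m=st.integers(1, 40),
    )
    def test_class_mix_invariance(self, acc_p, acc_m, n_p, n_m):
        """For fixed class-conditional accuracies the score is independent
        of the S+:S- mix in the window — the formula's purpose."""
        h = int(acc_p * n_p)
        cr = int(acc_m * n_m)
        outcomes = ["H"] * h + ["M"] * (n_p - h) + ["CR"] * cr + ["FA"] * (n_m - cr)
        expected = 0.5 * (h / n_p + cr / n_m)
        assert abs(performance(outcomes) - expected) < 1e-12


class TestSlidingPerformance:
    def test_constant_correct_log_scores_one(self):
        records = make_records(["H", "CR"] * 50)
        s = sliding_performance(gio.records_to_frame(records), 20)
        assert np.all(s.scores[19:] == 1.0)
        assert np.all(np.isnan(s.scores[:19]))

    def test_window_larger_than_log_leaves_all_undefined(self):
        records = make_records(["H", "CR"] * 5)
        s = sliding_performance(gio.records_to_frame(records), 20)
        assert np.all(np.isnan(s.scores))

    def test_single_class_window_is_undefined(self):
        records = make_records(["H"] * 30 + ["CR"] * 30)
        s = sliding_performance(gio.records_to_frame(records), 20)
        assert np.isnan(s.scores[19])  # all-S+ window
        assert np.isnan(s.scores[25])  # still all-S+
        assert not np.isnan(s.scores[30])  # first window containing a CR

    def test_valence_blind_log_hovers_at_half(self):
        rng = np.random.default_rng(0)
        valences = rng.permutation(["+"] * 5000 + ["-"] * 5000)
        outcomes = [
            ("H" if rng.random() < 0.5 else "M")
            if v == "+"
            else ("FA" if rng.random() < 0.5 else "CR")
            for v in valences
        ]
        s = sliding_performance(gio.records_to_frame(make_records(outcomes)), 100)
        assert abs(np.nanmean(s.scores) - 0.5) < 0.02

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_window_recount(self, seed):
        rng = np.random.default_rng(seed)
        outcomes = rng.choice(["H", "M", "CR", "FA"], size=60)
        s = sliding_performance(gio.records_to_frame(make_records(outcomes)), 10)
        for i in range(60):
            if i < 9:
                assert np.isnan(s.scores[i])
                continue
            expected = performance(outcomes[i - 9 : i + 1])
            if math.isnan(expected):
                assert np.isnan(s.scores[i])
            else:
                assert s.scores[i] == pytest.approx(expected, abs=1e-12)


class TestTrialsToCriterion:
    def test_perfect_responder_reaches_at_window(self):
        s = sliding_performance(gio.records_to_frame(make_records(["H", "CR"] * 50)), 20)
        assert trials_to_criterion(s, 0.8) == 20

    def test_never_reached_returns_marker(self):
        s = sliding_performance(gio.records_to_frame(make_records(["M", "CR"] * 50)), 20)
        assert trials_to_criterion(s, 0.8) is None

    def test_constructed_crossing_at_trial_57(self):
        """First 45 trials: misses on S+ (windows at 0.5); correct from 46
        on. The 6th correct S+ enters the 20-window at trial 57, putting the
        score at exactly 0.8 there and below before."""
        outcomes = [
            ("M" if i % 2 == 0 else "CR") if i < 45 else ("H" if i % 2 == 0 else "CR")
            for i in range(100)
        ]
        s = sliding_performance(gio.records_to_frame(make_records(outcomes)), 20)
        # independent oracle: explicit scan of trailing windows
        oracle = next(
            i + 1
            for i in range(19, 100)
            if not math.isnan(performance(outcomes[i - 19 : i + 1]))
            and performance(outcomes[i - 19 : i + 1]) >= 0.8
        )
        assert oracle == 57
        assert trials_to_criterion(s, 0.8) == 57

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 15))
    def test_prepending_correct_trials_cannot_delay_criterion(self, seed, k):
        """Prepending correct trials never delays the criterion beyond the
        trials added (window realignment can shift the crossing by at most
        the prefix length, never more), and a full window of correct
        prepended trials reaches criterion immediately."""
        rng = np.random.default_rng(seed)
        outcomes = list(rng.choice(["H", "M", "CR", "FA"], size=80))
        prefix = ["H", "CR"] * k
        t0 = trials_to_criterion(
            sliding_performance(gio.records_to_frame(make_records(outcomes)), 20), 0.8
        )
        t1 = trials_to_criterion(
            sliding_performance(
                gio.records_to_frame(make_records(prefix + outcomes)), 20
            ),
            0.8,
        )
        inf = float("inf")
        assert (t1 if t1 is not None else inf) <= (
            t0 + len(prefix) if t0 is not None else inf
        )
        if len(prefix) >= 20:
            assert t1 == 20


class TestSessions:
    def test_small_gaps_form_one_session(self):
        records = make_records(["H", "CR"] * 5, times=[i * 5.0 for i in range(10)])
        sset = segment_sessions(gio.records_to_frame(records))
        assert [s.length for s in sset.sessions] == [10]

    def test_large_gaps_split_every_trial(self):
        records = make_records(["H", "CR"] * 3, times=[i * 25.0 for i in range(6)])
        sset = segment_sessions(gio.records_to_frame(records))
        assert [s.length for s in sset.sessions] == [1] * 6

    def test_hand_partitioned_gap_pattern(self):
        """Gaps [5, 30, 5, 5, 30] over six trials -> sessions [2, 3, 1]."""
        gaps = [5, 30, 5, 5, 30]
        times = [0.0]
        for g in gaps:
            times.append(times[-1] + g)
        records = make_records(["H", "CR", "H", "CR", "H", "CR"], times=times)
        sset = segment_sessions(gio.records_to_frame(records))
        assert [s.length for s in sset.sessions] == [2, 3, 1]

    def test_sessions_partition_the_log(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.choice([4.0, 6.0, 30.0, 120.0], size=80))
        records = make_records(
            rng.choice(["H", "M", "CR", "FA"], size=80), times=list(times)
        )
        sset = segment_sessions(gio.records_to_frame(records))
        covered = []
        for s in sset.sessions:
            covered.extend(range(s.start_idx, s.start_idx + s.length))
        assert covered == list(range(80))

    def test_length_performance_pairs_exclude_undefined(self):
        records = make_records(["H", "H"], times=[0.0, 100.0])  # two 1-trial sessions
        sset = segment_sessions(gio.records_to_frame(records))
        assert sset.length_performance_pairs() == []


class TestHourlyProfiles:
    def test_all_trials_in_one_hour(self):
        records = make_records(["H", "CR"] * 10, times=[3 * 3600.0 + i for i in range(20)])
        prof = hourly_profiles(gio.records_to_frame(records))
        frac = prof["fractions"].loc["A1"]
        assert frac[3] == 1.0 and frac.drop(3).sum() == 0.0

    def test_uniform_log_night_fraction_half(self):
        times = [h * 3600.0 + 10.0 * i for h in range(24) for i in range(4)]
        records = make_records(["H", "CR"] * 48, times=sorted(times))
        prof = hourly_profiles(gio.records_to_frame(records))
        assert prof["night_fraction"].loc["A1"] == pytest.approx(0.5)

    def test_fractions_sum_to_one_per_animal(self):
        rng = np.random.default_rng(2)
        times = sorted(rng.uniform(0, 86400 * 3, size=500))
        records = make_records(rng.choice(["H", "CR"], size=500), times=times)
        prof = hourly_profiles(gio.records_to_frame(records))
        assert prof["fractions"].sum(axis=1).iloc[0] == pytest.approx(1.0, abs=1e-12)


class TestFastSlowSplit:
    @staticmethod
    def _log(accuracy, n=260, seed=0, animal="A1"):
        rng = np.random.default_rng(seed)
        outcomes = [
            ("H" if rng.random() < accuracy else "M")
            if i % 2 == 0
            else ("CR" if rng.random() < accuracy else "FA")
            for i in range(n)
        ]
        return gio.records_to_frame(make_records(outcomes, animal_id=animal))

    def test_two_animal_split_at_mean(self):
        series = {"slow1": self._log(0.6, seed=1), "fast1": self._log(0.9, seed=2)}
        out = fast_slow_split(series)
        assert out["groups"]["slow"] == ["slow1"]
        assert out["groups"]["fast"] == ["fast1"]
        assert out["split_threshold"] == pytest.approx(
            np.mean(list(out["early_performance"].values()))
        )

    def test_degenerate_identical_cohort_is_flagged(self):
        outcomes = ["H", "CR"] * 130
        series = {
            a: gio.records_to_frame(make_records(outcomes, animal_id=a))
            for a in ("A1", "A2", "A3")
        }
        with pytest.warns(UserWarning, match="degenerate"):
            out = fast_slow_split(series)
        assert out["degenerate"]

    def test_short_series_excluded_with_warning(self):
        series = {
            "ok1": self._log(0.7, seed=3),
            "ok2": self._log(0.8, seed=4),
            "short": self._log(0.7, n=50, seed=5),
        }
        with pytest.warns(UserWarning, match="short"):
            out = fast_slow_split(series)
        assert "short" not in out["early_performance"]

    def test_equal_asymptote_groups_have_similar_max_performance(self):
        """Fast and slow starters with a common ceiling end at comparable
        maximum accuracy."""
        rng = np.random.default_rng(6)
        series = {}
        for i in range(10):
            series[f"f{i}"] = self._log(0.93, seed=100 + i, animal=f"f{i}")
            series[f"s{i}"] = self._log(0.88, seed=200 + i, animal=f"s{i}")
        out = fast_slow_split(series)
        if "max_performance_ttest" in out:
            fast = np.mean(list(out["max_performance"]["fast"].values()))
            slow = np.mean(list(out["max_performance"]["slow"].values()))
            assert abs(fast - slow) < 0.1


class TestRewardTrialsCurve:
    def test_constant_intake_reference(self):
        data = {12.0: [340, 330], 24.0: [170, 165]}
        df = reward_trials_curve(data)
        row24 = df[df.reward_ul == 24.0].iloc[0]
        assert row24["normalized_trials"] == pytest.approx(0.5, abs=0.02)
        assert row24["reference"] == pytest.approx(0.5)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            reward_trials_curve({12.0: [300]})

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            reward_trials_curve({15.0: [300], 24.0: [150]})

    def test_half_reward_under_compensates(self):
        data = {12.0: [340], 6.0: [340 * 1.5]}  # capped, not doubled
        df = reward_trials_curve(data)
        row = df[df.reward_ul == 6.0].iloc[0]
        assert row["normalized_trials"] < 2.0
        assert row["deviation"] > 0


class TestTaskContextPooling:
    @staticmethod
    def _context_logs(accuracy, n_series, n=120, seed=0):
        rng = np.random.default_rng(seed)
        logs = []
        for k in range(n_series):
            outcomes = [
                ("H" if rng.random() < accuracy else "M")
                if i % 2 == 0
                else ("CR" if rng.random() < accuracy else "FA")
                for i in range(n)
            ]
            logs.append(gio.records_to_frame(make_records(outcomes, animal_id=f"a{k}")))
        return logs

    def test_distinct_contexts_detected(self):
        out = task_context_pooling(
            {
                "familiar": self._context_logs(0.95, 15, seed=1),
                "mixture": self._context_logs(0.65, 15, seed=2),
            }
        )
        assert out["anova_p"] < 0.01
        assert bool(out["tukey"].reject.any())

    def test_single_context_rejected(self):
        with pytest.raises(ValueError):
            task_context_pooling({"only": self._context_logs(0.9, 3)})

    def test_null_calibration_type_one_error(self):
        """Identical context distributions: the omnibus test rejects at
        roughly its nominal rate."""
        rng = np.random.default_rng(3)
        from scipy import stats as sps

        rejections = 0
        sims = 400
        for _ in range(sims):
            groups = [rng.normal(0.7, 0.05, size=8) for _ in range(3)]
            rejections += sps.f_oneway(*groups).pvalue < 0.05
        assert rejections / sims < 0.08
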