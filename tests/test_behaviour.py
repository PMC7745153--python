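"""Behavioural statistics: labels, metrics, contrasts, correlations, mood."""

import numpy as np
import pandas as pd
import pytest

import cudn
from cudn.behaviour import (
    contrast_high_low,
    cohort_metrics,
    good_choice_metrics,
    label_trials,
    mood_analysis,
    nu_performance_correlation,
    reversal_curve,
)
from cudn.hgf import HGFParams, RWParams, run_perceptual


class TestLabels:
    def test_partition_and_reset(self, default_schedule):
        labels = label_trials(default_schedule)
        assert len(labels) == 240
        assert set(labels["blame"]) <= {"high", "low"}
        starts = np.flatnonzero(default_schedule.is_reversal_start)
        assert np.all(labels["trials_since_reversal"].to_numpy()[starts] == 1)

    def test_single_block_counts_up(self):
        cfg = cudn.ScheduleConfig(correct_block_len_range=(240, 240))
        sch = cudn.generate_schedule(cfg)
        labels = label_trials(sch)
        assert np.array_equal(labels["trials_since_reversal"], np.arange(1, 241))


class TestMetrics:
    def test_always_good_agent(self, default_schedule):
        sch = default_schedule
        n = sch.n_trials
        sess = cudn.Session(
            "good", sch, sch.good_cue.copy(), np.ones(n, np.int64), np.zeros(n, np.int64),
            np.full(n, 0.5), np.where(sch.mood_probe, 0.0, np.nan),
        )
        m = good_choice_metrics(sess)
        assert m["good_choice_high"] == 1.0 and m["good_choice_low"] == 1.0

    def test_matches_brute_force(self, cudn_session):
        m = good_choice_metrics(cudn_session)
        labels = label_trials(cudn_session.schedule)
        mask = (labels["blame"] == "high").to_numpy()
        good = cudn_session.choice == cudn_session.schedule.good_cue
        assert m["good_choice_high"] == pytest.approx(good[mask].mean())
        assert m["accuracy_high"] == pytest.approx(cudn_session.correct[mask].mean())
        early = mask & (labels["trials_since_reversal"] <= 10).to_numpy()
        assert m["good_choice_early_high"] == pytest.approx(good[early].mean())

    def test_random_agents_near_chance(self):
        rng = np.random.default_rng(0)
        sessions = [
            cudn.simulate_random_session(
                cudn.generate_schedule(cudn.ScheduleConfig(seed=5000 + i)), seed=rng
            )
            for i in range(100)
        ]
        m = cohort_metrics(sessions)
        for col in ("good_choice_high", "good_choice_low", "accuracy_overall"):
            assert abs(m[col].mean() - 0.5) < 0.02


class TestContrast:
    def _metrics_frame(self, hi, lo):
        return pd.DataFrame({"x_high": hi, "x_low": lo})

    def test_identical_values_null(self):
        m = self._metrics_frame([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        c = contrast_high_low(m, "x")
        assert c.statistic == 0.0 and c.p_value == 1.0

    def test_constant_shift_significant(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.6, 0.05, 20)
        m = self._metrics_frame(base + 0.05 + rng.normal(0, 0.005, 20), base)
        c = contrast_high_low(m, "x")
        assert c.p_value < 0.001 and c.mean_high > c.mean_low
        assert c.ci_low > 0

    def test_wilcoxon_variant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(0.6, 0.05, 25)
        m = self._metrics_frame(base + 0.03 + rng.normal(0, 0.01, 25), base)
        c = contrast_high_low(m, "x", test="wilcoxon")
        assert c.p_value < 0.01
        assert c.effect_size > 0

    def test_too_few_pairs_rejected(self):
        m = self._metrics_frame([0.5], [0.4])
        with pytest.raises(ValueError):
            contrast_high_low(m, "x")

    def test_missing_pairs_excluded(self):
        m = self._metrics_frame([0.5, np.nan, 0.7, 0.6], [0.4, 0.5, np.nan, 0.5])
        c = contrast_high_low(m, "x")
        assert c.n == 2

    def test_type_i_error_calibration(self):
        # null simulation: paired samples with no true difference should
        # reject at ~ the nominal 5% level
        rng = np.random.default_rng(3)
        n_rep, n_sub = 500, 16
        rejections = 0
        for _ in range(n_rep):
            hi = rng.normal(0.6, 0.05, n_sub)
            lo = rng.normal(0.6, 0.05, n_sub)
            c = contrast_high_low(pd.DataFrame({"x_high": hi, "x_low": lo}), "x")
            rejections += c.p_value < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestReversalCurve:
    def test_learning_curve_increases(self, small_cohort):
        sessions, _ = small_cohort
        curve = reversal_curve(sessions, horizon=15, n_boot=100, seed=0)
        for cond in ("high", "low"):
            sub = curve[curve["blame"] == cond].sort_values("trials_since_reversal")
            first = sub["mean"].iloc[:3].mean()
            last = sub["mean"].iloc[-5:].mean()
            assert last > first

    def test_random_agent_flat(self):
        rng = np.random.default_rng(4)
        sessions = [
            cudn.simulate_random_session(
                cudn.generate_schedule(cudn.ScheduleConfig(seed=6000 + i)), seed=rng
            )
            for i in range(60)
        ]
        curve = reversal_curve(sessions, horizon=12, n_boot=50, seed=0)
        assert np.nanmax(np.abs(curve["mean"] - 0.5)) < 0.06

    def test_reports_n_subjects(self, small_cohort):
        sessions, _ = small_cohort
        curve = reversal_curve(sessions, horizon=25, n_boot=20, seed=0)
        assert (curve["n_subjects"] <= len(sessions)).all()


class TestNuCorrelation:
    def test_perfect_antimonotone(self):
        nu = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=[f"s{i}" for i in range(5)])
        metrics = pd.DataFrame(
            {
                "good_choice_early_high": [0.9, 0.8, 0.7, 0.6, 0.5],
                "good_choice_early_low": [0.5] * 5,
                "accuracy_high": [0.9, 0.8, 0.7, 0.6, 0.5],
                "accuracy_low": [0.5] * 5,
            },
            index=nu.index,
        )
        out = nu_performance_correlation(nu, metrics)
        full = out[(out["sample"] == "full")]
        assert np.allclose(full["rho"], -1.0)

    def test_degenerate_nu_flagged(self):
        nu = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        rng = np.random.default_rng(0)
        metrics = pd.DataFrame(
            {
                "good_choice_early_high": rng.random(6),
                "good_choice_early_low": rng.random(6),
                "accuracy_high": rng.random(6),
                "accuracy_low": rng.random(6),
            },
            index=nu.index,
        )
        out = nu_performance_correlation(nu, metrics)
        assert out["degenerate"].all()
        assert out["rho"].isna().all()

    def test_too_few_subjects_rejected(self):
        nu = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            nu_performance_correlation(nu, pd.DataFrame(index=nu.index))

    def test_generative_monotonicity(self):
        # larger true nu should produce larger performance enhancement
        def params(nu):
            return lambda rng: {"beta0": 1.5, "zeta": 0.8, "nu": nu, "alpha_rw": 0.4,
                                "omega": -2.6, "theta": 0.2, "lam": 0.0}

        rows = []
        for nu in (-0.5, 0.75, 2.0):
            sessions, _ = cudn.simulate_cohort(25, param_distribution=params(nu), seed=8)
            m = cohort_metrics(sessions)
            rows.append((m["accuracy_high"] - m["accuracy_low"]).mean())
        assert rows[0] < rows[2]


class TestMood:
    def _cohort_with_trajectories(self, w_blame, n=12, seed=0):
        mood_cfg = cudn.MoodConfig(w_blame=w_blame)
        sessions = []
        trajs = []
        rng_master = np.random.SeedSequence(seed).spawn(n)
        for i, ss in enumerate(rng_master):
            rng = np.random.default_rng(ss)
            sch = cudn.generate_schedule(cudn.ScheduleConfig(), rng=rng)
            sess = cudn.simulate_session(
                sch, HGFParams(omega=-2.6, theta=0.2), RWParams(alpha=0.4),
                cudn.ResponseParams(beta0=1.5, zeta=0.8, nu=1.0),
                seed=rng, subject_id=f"m{i}", mood_config=mood_cfg,
            )
            sessions.append(sess)
            trajs.append(run_perceptual(sess, HGFParams(omega=-2.6, theta=0.2), RWParams(alpha=0.4)))
        return sessions, trajs

    def test_negative_blame_effect_recovered(self):
        sessions, trajs = self._cohort_with_trajectories(w_blame=2.0)
        out = mood_analysis(sessions, trajs)
        assert out["mean_coef"] < 0
        assert out["p_value"] < 0.05

    def test_null_mood_generator_calibrated(self):
        sessions, trajs = self._cohort_with_trajectories(w_blame=0.0, seed=1)
        out = mood_analysis(sessions, trajs)
        assert out["p_value"] > 0.05

    def test_single_probe_rejected(self):
        cfg = cudn.ScheduleConfig(n_trials=8, correct_block_len_range=(8, 8),
                                  blame_block_len_range=(8, 8))
        sch = cudn.generate_schedule(cfg)
        sess = cudn.simulate_random_session(sch, seed=0)
        sess.mood[np.flatnonzero(sch.mood_probe)] = 1.0
        traj = run_perceptual(sess, HGFParams(), RWParams())
        with pytest.raises(ValueError):
            mood_analysis([sess], [traj])
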