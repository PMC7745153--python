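"""Perceptual models: HGF update correctness, RW properties, trajectory alignment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cudn
from cudn.hgf import (
    HGFParams,
    HGFState,
    RWParams,
    hgf_init,
    hgf_predict,
    hgf_update,
    rw_update,
    run_perceptual,
)


def reference_hgf_trajectory(outcomes, kappa, omega, theta,
                             mu2=0.0, mu3=1.0, s2=1.0, s3=1.0):
    """Independent straight-line recomputation of the 3-level binary filter.

    Written directly from the update equations, sharing no code with the
    implementation under test.
    """
    out = []
    for u in outcomes:
        v2 = math.exp(kappa * mu3 + omega)
        sigmahat2 = s2 + v2
        muhat1 = 1.0 / (1.0 + math.exp(-mu2))
        out.append((muhat1, sigmahat2))
        # level 2
        pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
        mu2_new = mu2 + (u - muhat1) / pi2
        s2_new = 1.0 / pi2
        # level 3
        pihat3 = 1.0 / (s3 + theta)
        w2 = v2 / sigmahat2
        da2 = (s2_new + (mu2_new - mu2) ** 2) / sigmahat2 - 1.0
        pi3 = pihat3 + 0.5 * kappa**2 * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
        mu3 = mu3 + 0.5 * kappa * w2 * da2 / pi3
        s3 = 1.0 / pi3
        mu2, s2 = mu2_new, s2_new
    return out


class TestPredict:
    def test_logistic_at_zero(self):
        p = HGFParams()
        pred = hgf_predict(hgf_init(p), p)
        assert pred.muhat1 == 0.5

    def test_known_logit(self):
        # logistic(ln 4) = 0.8
        p = HGFParams()
        state = HGFState(math.log(4.0), 1.0, 1.0, 1.0)
        assert hgf_predict(state, p).muhat1 == pytest.approx(0.8, abs=1e-12)

    def test_vanishing_volatility_increment(self):
        p = HGFParams(omega=-60.0)
        state = HGFState(0.0, 1.0, 0.7, 1.0)
        assert hgf_predict(state, p).sigmahat2 == pytest.approx(0.7, abs=1e-12)


class TestUpdate:
    def test_positive_prediction_error_raises_mu2(self):
        p = HGFParams()
        s0 = hgf_init(p)
        s1 = hgf_update(s0, p, 1)
        assert s1.mu2 > s0.mu2
        s1 = hgf_update(s0, p, 0)
        assert s1.mu2 < s0.mu2

    def test_non_binary_outcome_rejected(self):
        p = HGFParams()
        with pytest.raises(ValueError):
            hgf_update(hgf_init(p), p, 2)

    def test_matches_independent_recomputation(self):
        p = HGFParams(kappa=1.3, omega=-2.0, theta=0.4)
        outcomes = [1, 1, 0, 1, 0, 0, 1, 1, 1, 0]
        expected = reference_hgf_trajectory(outcomes, 1.3, -2.0, 0.4)
        state = hgf_init(p)
        for u, (muhat1, sigmahat2) in zip(outcomes, expected):
            pred = hgf_predict(state, p)
            assert pred.muhat1 == pytest.approx(muhat1, abs=1e-12)
            assert pred.sigmahat2 == pytest.approx(sigmahat2, abs=1e-12)
            state = hgf_update(state, p, u)

    def test_alternating_outcomes_settle_near_half(self):
        p = HGFParams(omega=-3.0, theta=0.1)
        state = hgf_init(p)
        preds = []
        for k in range(400):
            preds.append(hgf_predict(state, p).muhat1)
            state = hgf_update(state, p, k % 2)
        assert abs(np.mean(preds[-100:]) - 0.5) < 0.05

    def test_two_level_limit(self):
        # theta -> 0 with level 3 effectively pinned at its initial value
        # (tiny sigma3_0): the 3-level level-2 updates converge to the 2-level
        # filter with constant volatility exp(kappa*mu3_0+omega)
        outcomes = [1, 0, 1, 1, 0, 1, 0, 0, 1, 1] * 4
        p3 = HGFParams(omega=-2.5, theta=1e-14, sigma3_0=1e-12)
        p2 = HGFParams(omega=-2.5, theta=0.0)
        s3, s2 = hgf_init(p3), hgf_init(p2)
        for u in outcomes:
            s3 = hgf_update(s3, p3, u, levels=3)
            s2 = hgf_update(s2, p2, u, levels=2)
        assert s3.mu2 == pytest.approx(s2.mu2, abs=1e-8)
        assert s3.sigma2 == pytest.approx(s2.sigma2, abs=1e-8)

    @settings(max_examples=150, deadline=None)
    @given(
        omega=st.floats(-6.0, 0.0),
        theta=st.floats(0.001, 1.0),
        kappa=st.floats(0.2, 2.0),
        seed=st.integers(0, 10_000),
    )
    def test_variances_positive_or_loud_failure(self, omega, theta, kappa, seed):
        # invariant: whenever an update succeeds, every posterior variance is
        # strictly positive; pathological parameter regions fail loudly with
        # the documented error, never with a silent negative variance
        from cudn.hgf import ParameterPathologyError

        p = HGFParams(kappa=kappa, omega=omega, theta=theta)
        rng = np.random.default_rng(seed)
        state = hgf_init(p)
        for _ in range(60):
            try:
                state = hgf_update(state, p, int(rng.integers(0, 2)))
            except ParameterPathologyError:
                break
            assert state.sigma2 > 0 and state.sigma3 > 0
            assert hgf_predict(state, p).sigmahat2 > 0


class TestRW:
    def test_direct_substitution(self):
        p_new, delta = rw_update(0.5, 0.2, 1)
        assert p_new == pytest.approx(0.6)
        assert delta == pytest.approx(0.5)

    def test_zero_learning_rate(self):
        for blame in (0, 1):
            assert rw_update(0.37, 0.0, blame)[0] == 0.37

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            rw_update(0.5, 1.2, 1)

    @settings(max_examples=200, deadline=None)
    @given(
        p=st.floats(0.0, 1.0),
        alpha=st.floats(0.0, 1.0),
        blame=st.integers(0, 1),
    )
    def test_belief_stays_in_unit_interval(self, p, alpha, blame):
        p_new, _ = rw_update(p, alpha, blame)
        assert 0.0 <= p_new <= 1.0

    def test_monte_carlo_convergence(self):
        # i.i.d. blame at rate q=0.8, alpha=0.1: the stationary belief has
        # mean q and variance alpha*q*(1-q)/(2-alpha) (exact for the linear
        # recursion); after 500 wrong trials the empirical hit rates should
        # match the (approximately normal) stationary law
        rng = np.random.default_rng(0)
        q, alpha = 0.8, 0.1
        sd = np.sqrt(alpha * q * (1 - q) / (2 - alpha))
        n_rep = 1000
        terminal = np.empty(n_rep)
        for i in range(n_rep):
            p = 0.5
            draws = rng.random(500) < q
            for b in draws:
                p, _ = rw_update(p, alpha, int(b))
            terminal[i] = p
        assert abs(terminal.mean() - q) < 4 * sd / np.sqrt(n_rep)
        # ~72% mass within +-0.1 (1.09 sd) under the normal approximation
        from scipy.stats import norm

        expect = 2 * norm.cdf(0.1 / sd) - 1
        rate = np.mean(np.abs(terminal - q) <= 0.1)
        assert abs(rate - expect) < 0.06
        assert np.mean(np.abs(terminal - q) <= 3 * sd) >= 0.95


class TestTrajectory:
    def test_no_blame_keeps_prior(self, default_schedule):
        # all-correct agent: RW never invoked, blame belief constant at p0
        sch = default_schedule
        n = sch.n_trials
        sess = cudn.Session(
            "allcorrect",
            sch,
            choice=sch.good_cue.copy(),
            correct=np.ones(n, dtype=np.int64),
            blame=np.zeros(n, dtype=np.int64),
            rt=np.full(n, 0.5),
            mood=np.where(sch.mood_probe, 0.0, np.nan),
        )
        traj = run_perceptual(sess, HGFParams(), RWParams(alpha=0.3, p0=0.4))
        assert np.all(traj.pblame == 0.4)
        assert np.all(np.isnan(traj.delta_blame))

    def test_uncertainty_spikes_after_reversal(self):
        # the decision uncertainty should rise right after a reversal and
        # fall again with learning
        cfg = cudn.ScheduleConfig(correct_block_len_range=(40, 40), good_prob_levels=(0.8,), seed=21)
        sch = cudn.generate_schedule(cfg)
        sess = cudn.simulate_session(
            sch, HGFParams(omega=-2.6, theta=0.2), RWParams(),
            cudn.ResponseParams(beta0=2.0, zeta=0.5, nu=0.5), seed=5,
        )
        traj = run_perceptual(sess, HGFParams(omega=-2.6, theta=0.2), RWParams())
        u = traj.decision_uncertainty
        starts = np.flatnonzero(sch.is_reversal_start)[1:]  # skip session start
        post = np.array([u[s + 1 : s + 8].mean() for s in starts])
        pre = np.array([u[s - 6 : s].mean() for s in starts])
        assert np.mean(post > pre) > 0.7

    def test_no_lookahead(self, cudn_session):
        # permuting future feedback must not change the trial-k predictions
        s = cudn_session
        traj = run_perceptual(s, HGFParams(), RWParams())
        k = 120
        correct = s.correct.copy()
        blame = s.blame.copy()
        rng = np.random.default_rng(3)
        perm = rng.permutation(np.arange(k, s.n_trials))
        correct[k:] = correct[perm]
        blame[k:] = np.where(correct[k:] == 1, 0, blame[perm])
        mutated = cudn.Session(
            s.subject_id, s.schedule, s.choice.copy(), correct, blame, s.rt.copy(), s.mood.copy()
        )
        traj2 = run_perceptual(mutated, HGFParams(), RWParams())
        assert np.array_equal(traj.muhat1[: k + 1], traj2.muhat1[: k + 1])
        assert np.array_equal(traj.sigmahat2[: k + 1], traj2.sigmahat2[: k + 1])
        assert np.array_equal(traj.pblame[: k + 1], traj2.pblame[: k + 1])
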