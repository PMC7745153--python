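"""Perceptual learning models: binary hierarchical Gaussian filter and Rescorla-Wagner.

Two learning systems run in parallel over a session.  A three-level binary
hierarchical Gaussian filter (HGF) tracks the latent tendency of cue 1 to be
the correct cue: level 1 is the binary outcome ("cue 1 was correct"), level 2
is the logit-scale tendency ``x2`` with posterior mean ``mu2`` and variance
``sigma2``, and level 3 is the log-volatility of level 2.  The trial-wise
*estimation uncertainty* ``sigmahat2`` -- the prediction-time variance of the
level-2 belief, taken before the outcome is seen -- is what modulates decision
noise in the response model.

A Rescorla-Wagner (RW) learner tracks the conditional probability of blame
feedback given a wrong choice, ``p(blame|w)``.  Because blame can only be
observed after a wrong choice, the RW belief is updated only on wrong-choice
trials; on correct trials it carries over unchanged.

The HGF update equations follow the standard variational inversion of the
binary three-level model.  A two-level variant (constant volatility) is
obtained by freezing level 3 at its initial state; see :func:`hgf_update`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .task import Session

__all__ = [
    "HGFParams",
    "HGFState",
    "RWParams",
    "BeliefTrajectory",
    "ParameterPathologyError",
    "hgf_init",
    "hgf_predict",
    "hgf_update",
    "rw_update",
    "run_perceptual",
]

# Exponent guard for exp(kappa*mu3 + omega); keeps volatility finite when an
# optimizer or a pathological parameter draw pushes mu3 far out.
EXP_CLIP = 30.0

# Scale constant of the decision uncertainty (see
# BeliefTrajectory.decision_uncertainty): the delta-method variance of the
# value difference is multiplied by this unit so that response parameters of
# order one are meaningful.
UNCERTAINTY_UNIT = 8.0


class ParameterPathologyError(ValueError):
    """Raised when an HGF update produces a non-positive posterior precision."""


@dataclass(frozen=True)
class HGFParams:
    """Parameters of the binary three-level HGF.

    kappa
        Coupling strength from level 3 (log-volatility) to level 2.
    omega
        Tonic component of the level-2 log-volatility.
    theta
        Variance of the level-3 random walk (volatility of volatility).
    mu2_0, mu3_0, sigma2_0, sigma3_0
        Initial posterior means and variances of levels 2 and 3.
    """

    kappa: float = 1.0
    omega: float = -3.0
    theta: float = 0.02
    mu2_0: float = 0.0
    mu3_0: float = 1.0
    sigma2_0: float = 1.0
    sigma3_0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa > 0):
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not (self.theta >= 0):
            raise ValueError(f"theta must be >= 0, got {self.theta}")
        for name in ("sigma2_0", "sigma3_0"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


class HGFState(NamedTuple):
    """Posterior state of the HGF after seeing some number of outcomes."""

    mu2: float
    mu3: float
    sigma2: float
    sigma3: float


class Prediction(NamedTuple):
    """Pre-outcome predictions for one trial."""

    muhat1: float      # predicted p(cue 1 correct)
    sigmahat2: float   # prediction-time level-2 variance (estimation uncertainty)
    v2: float          # volatility increment exp(kappa*mu3 + omega)


@dataclass(frozen=True)
class RWParams:
    """Rescorla-Wagner learner for p(blame|w).

    ``alpha`` is the learning rate; ``p0`` the initial belief.  A fixed
    (non-learning) blame belief is the special case ``alpha = 0`` with ``p0``
    set to the fixed value.
    """

    alpha: float = 0.2
    p0: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError(f"p0 must be in [0, 1], got {self.p0}")


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def hgf_init(params: HGFParams) -> HGFState:
    """Initial belief state before any outcome."""
    return HGFState(params.mu2_0, params.mu3_0, params.sigma2_0, params.sigma3_0)


def hgf_predict(state: HGFState, params: HGFParams) -> Prediction:
    """Pre-outcome predictions: outcome probability and estimation uncertainty.

    ``muhat1 = logistic(mu2)`` and ``sigmahat2 = sigma2 + exp(kappa*mu3 + omega)``,
    i.e. the level-2 variance inflated by the current volatility estimate.
    The exponent is clipped at ``EXP_CLIP`` to guard against overflow.
    """
    v2 = math.exp(min(params.kappa * state.mu3 + params.omega, EXP_CLIP))
    # clamp away from exactly 0/1 so downstream logs and weights stay finite
    muhat1 = min(max(_sigmoid(state.mu2), 1e-12), 1.0 - 1e-12)
    return Prediction(muhat1, state.sigma2 + v2, v2)


def hgf_update(
    state: HGFState,
    params: HGFParams,
    outcome: int,
    levels: int = 3,
) -> HGFState:
    """One trial of the binary HGF update.

    ``outcome`` codes whether cue 1 was the correct cue this trial (0/1); the
    reciprocal task design makes this observable regardless of which cue was
    chosen.  With ``levels=2`` the third level is frozen, which leaves a
    two-level filter with constant volatility ``exp(kappa*mu3_0 + omega)``.

    Raises
    ------
    ValueError
        If ``outcome`` is not binary or ``levels`` not in {2, 3}.
    ParameterPathologyError
        If the level-3 posterior precision is non-positive, which signals a
        pathological parameter regime.
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    if levels not in (2, 3):
        raise ValueError(f"levels must be 2 or 3, got {levels}")

    muhat1, sigmahat2, v2 = hgf_predict(state, params)

    # level-2 update
    delta1 = outcome - muhat1
    pi2 = 1.0 / sigmahat2 + muhat1 * (1.0 - muhat1)
    mu2_new = state.mu2 + delta1 / pi2
    sigma2_new = 1.0 / pi2

    if levels == 2:
        return HGFState(mu2_new, state.mu3, sigma2_new, state.sigma3)

    # level-3 update driven by the level-2 volatility prediction error
    pihat3 = 1.0 / (state.sigma3 + params.theta)
    w2 = v2 / sigmahat2
    delta2 = (sigma2_new + (mu2_new - state.mu2) ** 2) / sigmahat2 - 1.0
    k = params.kappa
    pi3 = pihat3 + 0.5 * k * k * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
    if pi3 <= 0:
        raise ParameterPathologyError(
            f"non-positive level-3 posterior precision ({pi3:.3g}); "
            "parameters are in a pathological regime"
        )
    mu3_new = state.mu3 + 0.5 * k * w2 * delta2 / pi3
    return HGFState(mu2_new, mu3_new, sigma2_new, 1.0 / pi3)


def rw_update(p: float, alpha: float, blame_observed: int) -> tuple[float, float]:
    """Rescorla-Wagner update of the blame belief on a wrong-choice trial.

    Returns ``(p_new, delta)`` where ``delta = blame_observed - p`` is the
    blame prediction error (BPE) and ``p_new = p + alpha * delta``.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if blame_observed not in (0, 1):
        raise ValueError(f"blame_observed must be 0 or 1, got {blame_observed!r}")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    delta = blame_observed - p
    return p + alpha * delta, delta


@dataclass
class BeliefTrajectory:
    """Per-trial belief trajectories of the two learners over one session.

    All quantities indexed by trial ``k`` are the *pre-outcome* values used by
    the response model at trial ``k``: ``muhat1[k]`` and ``sigmahat2[k]`` are
    the HGF predictions before trial-k feedback, and ``pblame[k]`` is the
    blame belief before trial-k feedback.  ``delta_blame[k]`` is the blame
    prediction error (NaN on trials where blame was unobservable, i.e. the
    choice was correct).  The raw posterior states (``mu2`` ... ``sigma3``)
    are the post-update values after trial ``k``.
    """

    muhat1: np.ndarray
    sigmahat2: np.ndarray
    pblame: np.ndarray
    delta_blame: np.ndarray
    mu2: np.ndarray
    mu3: np.ndarray
    sigma2: np.ndarray
    sigma3: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.muhat1)
        for name in ("sigmahat2", "pblame", "delta_blame", "mu2", "mu3", "sigma2", "sigma3"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"trajectory field {name} has inconsistent length")
        if np.any((self.muhat1 <= 0) | (self.muhat1 >= 1)):
            raise ValueError("muhat1 must lie strictly inside (0, 1)")
        if np.any((self.pblame < 0) | (self.pblame > 1)):
            raise ValueError("pblame must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.muhat1)

    @property
    def decision_uncertainty(self) -> np.ndarray:
        """Normalized estimation uncertainty of the decision variable, per trial.

        The softmax acts on the value difference between the cues,
        ``2*muhat1 - 1``; by the delta method its estimation variance is
        ``4 * [muhat1*(1-muhat1)]**2 * sigmahat2``.  The measure used by the
        response model is this variance times the unit constant
        ``UNCERTAINTY_UNIT`` (8, i.e. the value 2 in the fully ignorant state
        ``muhat1 = 0.5``, ``sigmahat2 = 1``):

            u = 32 * [muhat1*(1-muhat1)]**2 * sigmahat2.

        The unit is a scale convention for the response parameters zeta and
        nu: it is chosen so that suppression strengths nu of order one
        produce blame effects of the size the behavioural data show (see
        docs/methods.md).  The uncertainty is maximal just after a
        probability reversal (when ``muhat1`` passes through 0.5 and the
        volatility estimate rises) and shrinks with learning.
        """
        w1 = self.muhat1 * (1.0 - self.muhat1)
        return UNCERTAINTY_UNIT * 4.0 * w1 * w1 * self.sigmahat2


def run_perceptual(
    session: "Session",
    hgf: HGFParams,
    rw: RWParams,
    levels: int = 3,
) -> BeliefTrajectory:
    """Run both learners over a complete session and return their trajectories.

    The loop is strictly causal: the predictions stored at trial ``k`` are
    computed before trial-``k`` feedback enters either learner, so the decision
    at ``k`` never sees its own outcome.  The HGF consumes the binary series
    "cue 1 was correct" (derivable for every trial from the chosen cue and the
    correct/wrong feedback because the task's correct probabilities are
    reciprocal); the RW learner consumes blame feedback on wrong trials only.
    """
    n = session.n_trials
    u = session.cue1_correct
    corrects = session.correct
    blames = session.blame
    if np.any(~np.isin(corrects, (0, 1))) or np.any(~np.isin(session.choice, (1, 2))):
        raise ValueError("session has missing or invalid feedback/choice rows")

    muhat1 = np.empty(n)
    sigmahat2 = np.empty(n)
    pblame = np.empty(n)
    delta_blame = np.full(n, np.nan)
    mu2 = np.empty(n)
    mu3 = np.empty(n)
    sigma2 = np.empty(n)
    sigma3 = np.empty(n)

    state = hgf_init(hgf)
    pb = rw.p0
    for k in range(n):
        pred = hgf_predict(state, hgf)
        muhat1[k] = pred.muhat1
        sigmahat2[k] = pred.sigmahat2
        pblame[k] = pb
        state = hgf_update(state, hgf, int(u[k]), levels=levels)
        if corrects[k] == 0:
            pb, delta_blame[k] = rw_update(pb, rw.alpha, int(blames[k]))
        mu2[k], mu3[k], sigma2[k], sigma3[k] = state

    return BeliefTrajectory(muhat1, sigmahat2, pblame, delta_blame, mu2, mu3, sigma2, sigma3)
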