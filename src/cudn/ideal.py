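"""Ideal Bayesian observer benchmark for the reversal task.

The observer knows the task's generative structure: the latent per-trial
probability that cue 1 is correct lives on the four levels {0.2, 0.3, 0.7,
0.8}, and at every trial the level jumps with a constant hazard ``h`` to one
of the two levels on the *opposite* side of 0.5 (the alternating-reversal
design), staying put otherwise.  The constant hazard is the Markov
approximation of the uniform 10-50-trial block lengths; its default is the
reciprocal of the mean block length, ``h = 1/30``.  Each trial the observer
sees which cue was actually correct (knowable for both cues because the
correct probabilities are reciprocal) and performs an exact HMM filter
update.  Blame plays no role: it only affects the consequences of wrong
choices, never which cue is better.

Two response policies are provided:

``greedy``
    Choose cue 1 iff the predictive probability that cue 1 is correct
    exceeds 0.5 (ties broken uniformly) -- the reward-maximizing policy.
``matching``
    Posterior matching / Thompson sampling: draw a latent level from the
    predictive belief and choose the cue on that level's good side, i.e.
    choose cue 1 with probability equal to the posterior probability that
    cue 1 is the better cue.

An ideal-learner reference for this task sits only slightly above human
performance (~70% good choices), far below what the greedy policy attains
(~82% under any plausible hazard), so the ``matching`` policy -- the
canonical parameter-free stochastic benchmark -- is the default for
:func:`benchmark_good_choice`; see ``docs/methods.md`` for the hazard and
policy sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import ScheduleConfig, TaskSchedule, generate_schedule

__all__ = [
    "STATE_LEVELS",
    "HMMBelief",
    "transition_matrix",
    "ideal_update",
    "ideal_predict",
    "ideal_policy",
    "matching_policy",
    "run_ideal_session",
    "benchmark_good_choice",
]

#: latent levels of p(cue 1 correct) used by the observer (the task's design levels)
STATE_LEVELS = np.array([0.2, 0.3, 0.7, 0.8])

DEFAULT_HAZARD = 1.0 / 30.0


@dataclass
class HMMBelief:
    """Posterior over the latent correct-probability level, plus the hazard."""

    probs: np.ndarray
    hazard: float = DEFAULT_HAZARD

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != STATE_LEVELS.shape:
            raise ValueError("belief must have one probability per latent level")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-8) or np.any(self.probs < 0):
            raise ValueError("belief probabilities must be non-negative and sum to 1")
        if not (0.0 <= self.hazard <= 1.0):
            raise ValueError("hazard must lie in [0, 1]")

    @classmethod
    def uniform(cls, hazard: float = DEFAULT_HAZARD) -> "HMMBelief":
        return cls(np.full(len(STATE_LEVELS), 1.0 / len(STATE_LEVELS)), hazard)

    @property
    def p_cue1_good(self) -> float:
        """Posterior probability that cue 1 is the designed better cue."""
        return float(self.probs[STATE_LEVELS > 0.5].sum())


def transition_matrix(hazard: float) -> np.ndarray:
    """Per-trial latent transition kernel: opposite-side jumps at rate ``hazard``."""
    K = len(STATE_LEVELS)
    T = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            same_side = (STATE_LEVELS[i] > 0.5) == (STATE_LEVELS[j] > 0.5)
            if same_side:
                T[i, j] = (1.0 - hazard) if i == j else 0.0
            else:
                T[i, j] = hazard / 2.0
    return T


def ideal_predict(belief: HMMBelief) -> tuple[np.ndarray, float]:
    """Propagate the belief one step; return (predictive state probs, P(cue1 correct))."""
    bp = belief.probs @ transition_matrix(belief.hazard)
    return bp, float(bp @ STATE_LEVELS)


def ideal_update(belief: HMMBelief, observation: int) -> HMMBelief:
    """Transition step followed by a Bayes update with the trial's correct cue.

    ``observation`` is 1 if cue 1 was the correct cue this trial, else 0.
    """
    if observation not in (0, 1):
        raise ValueError(f"observation must be 0 or 1, got {observation!r}")
    bp, _ = ideal_predict(belief)
    lik = STATE_LEVELS if observation == 1 else 1.0 - STATE_LEVELS
    post = bp * lik
    return HMMBelief(post / post.sum(), belief.hazard)


def ideal_policy(belief: HMMBelief, rng: np.random.Generator) -> int:
    """Greedy policy: the cue with higher predictive correct probability."""
    _, p1 = ideal_predict(belief)
    if p1 > 0.5:
        return 1
    if p1 < 0.5:
        return 2
    return int(rng.integers(1, 3))


def matching_policy(belief: HMMBelief, rng: np.random.Generator) -> int:
    """Posterior matching: sample a latent level from the predictive belief and
    choose the better cue under that level (equivalently, choose cue 1 with
    probability equal to the predictive probability that cue 1 is good)."""
    bp, _ = ideal_predict(belief)
    p_good1 = float(bp[STATE_LEVELS > 0.5].sum())
    return 1 if rng.random() < p_good1 else 2


_POLICIES = {"greedy": ideal_policy, "matching": matching_policy}


def run_ideal_session(
    schedule: TaskSchedule,
    rng: np.random.Generator,
    hazard: float = DEFAULT_HAZARD,
    policy: str = "matching",
) -> float:
    """Run the observer through one schedule; return its good-choice proportion.

    Each trial: propagate the belief, choose via the policy, then observe the
    realized correct cue and update.  The observer never sees trial-k feedback
    before its trial-k choice.
    """
    if policy not in _POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {sorted(_POLICIES)}")
    T = transition_matrix(hazard)
    probs = np.full(len(STATE_LEVELS), 1.0 / len(STATE_LEVELS))
    n_good = 0
    good_side = STATE_LEVELS > 0.5
    for k in range(schedule.n_trials):
        bp = probs @ T
        if policy == "greedy":
            p1 = bp @ STATE_LEVELS
            choice = 1 if p1 > 0.5 else (2 if p1 < 0.5 else int(rng.integers(1, 3)))
        else:
            choice = 1 if rng.random() < bp[good_side].sum() else 2
        if choice == schedule.good_cue[k]:
            n_good += 1
        obs = 1 if rng.random() < schedule.p_correct_cue1[k] else 0
        lik = STATE_LEVELS if obs else 1.0 - STATE_LEVELS
        probs = bp * lik
        probs /= probs.sum()
    return n_good / schedule.n_trials


def benchmark_good_choice(
    config: ScheduleConfig | None = None,
    n_sessions: int = 300,
    seed: int = 0,
    hazard: float = DEFAULT_HAZARD,
    policy: str = "matching",
) -> tuple[float, float]:
    """Mean good-choice proportion of the ideal observer over fresh schedules.

    Returns ``(mean, standard_error)`` across ``n_sessions`` independently
    generated schedules (each with freshly sampled outcomes).
    """
    if config is None:
        config = ScheduleConfig()
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    rng = np.random.default_rng(seed)
    props = np.empty(n_sessions)
    for i in range(n_sessions):
        schedule = generate_schedule(config, rng=rng)
        props[i] = run_ideal_session(schedule, rng, hazard=hazard, policy=policy)
    return float(props.mean()), float(props.std(ddof=1) / np.sqrt(n_sessions))
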