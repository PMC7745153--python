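"""Probabilistic reversal-learning task with blame feedback: schedules, sessions, cohorts.

The task has 240 trials.  On every trial one of two cues is "correct"; the
probability that cue 1 is correct is drawn per block from {0.7, 0.8} (or the
reciprocal {0.3, 0.2} when cue 2 is the good cue) and the good cue flips at
every block boundary, with block lengths uniform on 10-50 trials.
Independently, the conditional probability of blame feedback after a *wrong*
choice alternates between high (0.8 or 0.9) and low (0.1 or 0.2) blocks of
20-40 trials.  Mood is probed every 8th trial on a -3..3 scale (30 probes in
a 240-trial session).

Simulated agents choose according to the generative CUDN model (or any other
member of the candidate space): a hierarchical Gaussian filter tracks
p(correct|cue), a Rescorla-Wagner learner tracks p(blame|w), and choices are
sampled from the uncertainty-modulated softmax.  Response times and mood
ratings are generated by simple descriptive models documented in
``docs/methods.md`` (the experiment itself has no mechanistic RT or mood
model): log-RT increases linearly with the deliberation index
``pblame * decision_uncertainty``, and mood decreases with the current blame
belief and increases with the recent correct rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import hgf as _hgf
from .hgf import HGFParams, RWParams, hgf_init, hgf_predict, hgf_update, rw_update
from .response import ModelSpec, ResponseParams, choice_probability, cudn_spec, inverse_temperature

__all__ = [
    "ScheduleConfig",
    "TaskSchedule",
    "Session",
    "RTConfig",
    "MoodConfig",
    "CohortPriors",
    "generate_schedule",
    "sample_feedback",
    "simulate_session",
    "simulate_random_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Generative structure of one task session (defaults are the study design)."""

    n_trials: int = 240
    correct_block_len_range: tuple[int, int] = (10, 50)
    good_prob_levels: tuple[float, ...] = (0.7, 0.8)
    blame_block_len_range: tuple[int, int] = (20, 40)
    blame_high_levels: tuple[float, ...] = (0.8, 0.9)
    blame_low_levels: tuple[float, ...] = (0.1, 0.2)
    mood_probe_period: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be > 0")
        for name in ("correct_block_len_range", "blame_block_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        for name in ("good_prob_levels", "blame_high_levels", "blame_low_levels"):
            if any(not (0.0 < p < 1.0) for p in getattr(self, name)):
                raise ValueError(f"all {name} must lie in (0, 1)")
        if any(p <= 0.5 for p in self.good_prob_levels):
            raise ValueError("good_prob_levels must exceed 0.5")
        if self.mood_probe_period <= 0:
            raise ValueError("mood_probe_period must be > 0")
        if self.n_trials % self.mood_probe_period != 0:
            warnings.warn(
                "n_trials is not divisible by mood_probe_period; "
                "the final inter-probe interval is truncated",
                stacklevel=2,
            )


@dataclass
class TaskSchedule:
    """Realized per-trial generative probabilities and block structure."""

    config: ScheduleConfig
    p_correct_cue1: np.ndarray      # probability cue 1 is the correct cue
    p_blame_given_wrong: np.ndarray
    good_cue: np.ndarray            # 1 or 2, the designed better cue
    blame_block_label: np.ndarray   # 'high' / 'low'
    is_reversal_start: np.ndarray   # True on the first trial of each correct-prob block
    mood_probe: np.ndarray          # True on probe trials

    def __post_init__(self) -> None:
        n = self.config.n_trials
        for name in (
            "p_correct_cue1",
            "p_blame_given_wrong",
            "good_cue",
            "blame_block_label",
            "is_reversal_start",
            "mood_probe",
        ):
            if len(getattr(self, name)) != n:
                raise ValueError(f"schedule field {name} has length != n_trials")
        expected_good = np.where(self.p_correct_cue1 > 0.5, 1, 2)
        if not np.array_equal(expected_good, self.good_cue):
            raise ValueError("good_cue must be the cue with p_correct > 0.5")

    @property
    def n_trials(self) -> int:
        return self.config.n_trials

    def p_correct(self, cue: int):
        """Per-trial correct probability of ``cue`` (reciprocal design)."""
        if cue == 1:
            return self.p_correct_cue1
        if cue == 2:
            return 1.0 - self.p_correct_cue1
        raise ValueError(f"cue must be 1 or 2, got {cue!r}")


def _block_lengths(rng: np.random.Generator, n_trials: int, len_range: tuple[int, int]) -> list[int]:
    lo, hi = len_range
    lengths: list[int] = []
    total = 0
    while total < n_trials:
        L = int(rng.integers(lo, hi + 1))
        L = min(L, n_trials - total)  # final block truncated at session end
        lengths.append(L)
        total += L
    return lengths


def generate_schedule(config: ScheduleConfig, rng: np.random.Generator | None = None) -> TaskSchedule:
    """Generate one task schedule; deterministic given ``config.seed`` (or ``rng``).

    Correct-probability blocks have uniformly drawn lengths and good-cue
    probability levels; the good cue alternates at every block boundary
    (a reversal).  Blame blocks are drawn independently, alternating high and
    low labels with the level drawn uniformly within the label's set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_trials

    p1 = np.empty(n)
    good = np.empty(n, dtype=np.int64)
    rev = np.zeros(n, dtype=bool)
    good_cue = int(rng.integers(1, 3))
    t = 0
    for L in _block_lengths(rng, n, config.correct_block_len_range):
        level = float(rng.choice(config.good_prob_levels))
        p1[t : t + L] = level if good_cue == 1 else 1.0 - level
        good[t : t + L] = good_cue
        rev[t] = True
        good_cue = 3 - good_cue
        t += L

    pbl = np.empty(n)
    label = np.empty(n, dtype=object)
    high = bool(rng.integers(0, 2))
    t = 0
    for L in _block_lengths(rng, n, config.blame_block_len_range):
        levels = config.blame_high_levels if high else config.blame_low_levels
        pbl[t : t + L] = float(rng.choice(levels))
        label[t : t + L] = "high" if high else "low"
        high = not high
        t += L

    probes = (np.arange(1, n + 1) % config.mood_probe_period) == 0
    return TaskSchedule(config, p1, pbl, good, label.astype("U4"), rev, probes)


def sample_feedback(
    schedule: TaskSchedule,
    k: int,
    choice: int,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Sample (correct_feedback, blame_feedback) for choosing ``choice`` at trial ``k``.

    A single latent draw decides which cue is correct this trial (the
    reciprocal design); the chosen cue yields correct feedback iff it is that
    cue.  Blame can only follow a wrong choice, with the scheduled conditional
    probability.
    """
    if choice not in (1, 2):
        raise ValueError(f"choice must be 1 or 2, got {choice!r}")
    if not (0 <= k < schedule.n_trials):
        raise IndexError(f"trial index {k} outside schedule")
    winner = 1 if rng.random() < schedule.p_correct_cue1[k] else 2
    correct = int(choice == winner)
    blame = int(correct == 0 and rng.random() < schedule.p_blame_given_wrong[k])
    return correct, blame


@dataclass
class Session:
    """One subject's trial-by-trial data (observed or simulated)."""

    subject_id: str
    schedule: TaskSchedule
    choice: np.ndarray   # 1 or 2
    correct: np.ndarray  # 0/1 correct feedback
    blame: np.ndarray    # 0/1 blame feedback (only possible on wrong trials)
    rt: np.ndarray       # seconds
    mood: np.ndarray     # float; rating in [-3, 3] on probe trials, NaN otherwise

    def __post_init__(self) -> None:
        n = self.schedule.n_trials
        for name in ("choice", "correct", "blame", "rt", "mood"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"session field {name} has length != n_trials")
        if np.any((self.blame == 1) & (self.correct == 1)):
            raise ValueError("blame feedback cannot occur on correct trials")
        on_probe = ~np.isnan(self.mood)
        if not np.array_equal(on_probe, self.schedule.mood_probe):
            raise ValueError("mood must be present exactly on mood-probe trials")

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials

    @property
    def cue1_correct(self) -> np.ndarray:
        """Binary series "cue 1 was the correct cue", derived from own feedback.

        Valid for every trial because the correct probabilities of the two
        cues are reciprocal, so the outcome of the unchosen cue is knowable.
        """
        return np.where(self.choice == 1, self.correct, 1 - self.correct).astype(np.int64)


@dataclass(frozen=True)
class RTConfig:
    """Log-normal response-time generator.

    ``log rt = mu + kappa * D + eps`` with ``eps ~ N(0, sigma^2)`` and
    deliberation index ``D = pblame * decision_uncertainty``; ``kappa > 0``
    reproduces the direction of slower responding under high blame
    expectation.  Defaults give a ~0.58 s baseline with a few-percent blame
    effect.
    """

    mu: float = math.log(0.58)
    kappa: float = 0.06
    sigma: float = 0.25


@dataclass(frozen=True)
class MoodConfig:
    """Synthetic mood-probe generator.

    ``mood = round(clip(m0 - w_blame * pblame + w_outcome * recent_correct
    + noise, -3, 3))`` where ``recent_correct`` is the correct rate over the
    last ``window`` trials.  ``w_blame > 0`` builds in the negative effect of
    blame expectation on mood.
    """

    m0: float = 0.0
    w_blame: float = 2.0
    w_outcome: float = 2.0
    window: int = 8
    sigma: float = 0.8


def simulate_session(
    schedule: TaskSchedule,
    hgf_params: HGFParams,
    rw_params: RWParams,
    response_params: ResponseParams,
    spec: ModelSpec | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    rt_config: RTConfig = RTConfig(),
    mood_config: MoodConfig = MoodConfig(),
) -> Session:
    """Forward-simulate one agent through a schedule under a generative model.

    The agent's choices are sampled from the model's trial-wise choice
    probabilities, computed from beliefs updated with the sampled feedback;
    RT and mood are sampled from the descriptive generators above.
    Reproducible given the seed.
    """
    if spec is None:
        spec = cudn_spec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials

    choice = np.empty(n, dtype=np.int64)
    correct = np.empty(n, dtype=np.int64)
    blame = np.empty(n, dtype=np.int64)
    rt = np.empty(n)
    mood = np.full(n, np.nan)

    state = hgf_init(hgf_params)
    pb = rw_params.p0
    for k in range(n):
        muhat1, sigmahat2, _ = hgf_predict(state, hgf_params)
        w1 = muhat1 * (1.0 - muhat1)
        uncertainty = _hgf.UNCERTAINTY_UNIT * 4.0 * w1 * w1 * sigmahat2
        beta = float(inverse_temperature(uncertainty, pb, response_params, spec))
        if spec.blame_effect == "value":
            u1 = muhat1 + response_params.lam * (1.0 - muhat1) * pb
            u2 = (1.0 - muhat1) + response_params.lam * muhat1 * pb
        else:
            u1, u2 = muhat1, 1.0 - muhat1
        p1, _p2 = choice_probability((u1, u2), beta)
        c = 1 if rng.random() < float(p1) else 2
        co, bl = sample_feedback(schedule, k, c, rng)
        choice[k], correct[k], blame[k] = c, co, bl

        D = pb * uncertainty  # deliberation index: blame belief x decision uncertainty
        rt[k] = math.exp(rt_config.mu + rt_config.kappa * D + rng.normal(0.0, rt_config.sigma))
        if schedule.mood_probe[k]:
            lo = max(0, k - mood_config.window + 1)
            recent = float(np.mean(correct[lo : k + 1]))
            raw = (
                mood_config.m0
                - mood_config.w_blame * pb
                + mood_config.w_outcome * recent
                + rng.normal(0.0, mood_config.sigma)
            )
            mood[k] = float(np.clip(round(raw), -3, 3))

        u = 1 if (c == 1) == bool(co) else 0
        state = hgf_update(state, hgf_params, u, levels=spec.hgf_levels)
        if co == 0 and spec.blame_learning == "rw":
            pb, _ = rw_update(pb, rw_params.alpha, bl)

    return Session(subject_id, schedule, choice, correct, blame, rt, mood)


def simulate_random_session(
    schedule: TaskSchedule,
    seed: int | np.random.Generator = 0,
    subject_id: str = "rand",
) -> Session:
    """A uniform-random agent (chance floor); RT log-normal, mood noise only."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = schedule.n_trials
    choice = rng.integers(1, 3, size=n)
    winner = np.where(rng.random(n) < schedule.p_correct_cue1, 1, 2)
    correct = (choice == winner).astype(np.int64)
    blame = ((correct == 0) & (rng.random(n) < schedule.p_blame_given_wrong)).astype(np.int64)
    rt = np.exp(math.log(0.58) + rng.normal(0.0, 0.25, size=n))
    mood = np.full(n, np.nan)
    probes = np.flatnonzero(schedule.mood_probe)
    mood[probes] = np.clip(np.round(rng.normal(0.0, 1.0, size=probes.size)), -3, 3)
    return Session(subject_id, schedule, choice, correct, blame, rt, mood)


@dataclass(frozen=True)
class CohortPriors:
    """Population distribution from which simulated agents' parameters are drawn.

    Gaussian in the natural fitting space of each parameter (log for zeta and
    theta, logit for alpha_rw, identity otherwise), truncated at two standard
    deviations to keep every agent inside the filter's well-behaved regime.

    The defaults are the package's study conditions: they produce cohorts
    whose group behaviour resembles the experiment (overall good-choice
    proportion ~0.68, accuracy ~0.59, and a positive high-minus-low blame
    enhancement of early-window good choice and accuracy), with a positive
    mean suppression parameter ``nu ~ N(1, 0.5^2)``; see ``docs/methods.md``
    for how each value was chosen.
    """

    beta0: tuple[float, float] = (1.5, 0.4)
    log_zeta: tuple[float, float] = (math.log(0.75), 0.5)
    nu: tuple[float, float] = (1.0, 0.5)
    logit_alpha_rw: tuple[float, float] = (-0.4, 0.35)
    omega: tuple[float, float] = (-2.6, 0.25)
    log_theta: tuple[float, float] = (math.log(0.2), 0.3)
    lam: tuple[float, float] = (-1.0, 0.5)

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw one agent's native-space parameters (2-sd truncated normals)."""

        def draw(ms: tuple[float, float]) -> float:
            m, sd = ms
            return float(np.clip(rng.normal(m, sd), m - 2 * sd, m + 2 * sd))

        return {
            "beta0": draw(self.beta0),
            "zeta": math.exp(draw(self.log_zeta)),
            "nu": draw(self.nu),
            "alpha_rw": 1.0 / (1.0 + math.exp(-draw(self.logit_alpha_rw))),
            "omega": draw(self.omega),
            "theta": math.exp(draw(self.log_theta)),
            "lam": draw(self.lam),
        }


def _params_from_dict(p: dict[str, float], spec: ModelSpec) -> tuple[HGFParams, RWParams, ResponseParams]:
    hgf_params = HGFParams(omega=p["omega"], theta=p.get("theta", 0.3))
    if spec.blame_learning == "rw":
        rw_params = RWParams(alpha=p["alpha_rw"], p0=0.5)
    else:
        rw_params = RWParams(alpha=0.0, p0=p.get("p_blame0", 0.5))
    response_params = ResponseParams(
        beta0=p["beta0"], zeta=p["zeta"], nu=p.get("nu", 0.0), lam=p.get("lam", 0.0)
    )
    return hgf_params, rw_params, response_params


def simulate_cohort(
    n_subjects: int,
    param_distribution: CohortPriors | Callable[[np.random.Generator], dict[str, float]] | None = None,
    config: ScheduleConfig | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort of agents: independent schedules and sessions per subject.

    Per-subject RNG streams are spawned from ``numpy.random.SeedSequence(seed)``
    so the cohort is reproducible and subjects are independent.  Returns the
    sessions and a table of true generative parameters (for recovery studies).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if config is None:
        config = ScheduleConfig()
    if spec is None:
        spec = cudn_spec()
    if param_distribution is None:
        param_distribution = CohortPriors()
    sampler = (
        param_distribution.sample
        if isinstance(param_distribution, CohortPriors)
        else param_distribution
    )

    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    sessions: list[Session] = []
    rows: list[dict[str, float | str]] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        params = sampler(rng)
        schedule = generate_schedule(config, rng=rng)
        hgf_params, rw_params, response_params = _params_from_dict(params, spec)
        sid = f"sub{i + 1:03d}"
        sessions.append(
            simulate_session(
                schedule, hgf_params, rw_params, response_params, spec, seed=rng, subject_id=sid
            )
        )
        rows.append({"subject_id": sid, **params})
    return sessions, pd.DataFrame(rows).set_index("subject_id")
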