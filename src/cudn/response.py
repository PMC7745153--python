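"""Response models: uncertainty-modulated softmax choice and the candidate model space.

The central object is the CUDN ("control of uncertainty-induced decision
noise") response model.  Choices between the two cues follow a softmax over
the predicted correct probabilities, with a trial-wise inverse temperature

    beta^(k) = exp( beta0 - (zeta - nu * pblame^(k)) * s^(k) )

where ``s^(k)`` is the trial's estimation uncertainty about the decision
variable (``BeliefTrajectory.decision_uncertainty``: the delta-method
estimation variance of the value difference between the cues, normalized to
1 in the fully ignorant state, and maximal just after probability
reversals).
Uncertainty *lowers* the inverse temperature (uncertainty-induced decision
noise, UDN, scaled by ``zeta``), while the learned blame belief ``pblame``
*suppresses* that uncertainty effect in proportion to ``nu``.  The
suppression is exactly proportional to the current uncertainty: on the log
scale, d log beta / d pblame = nu * s.

Alternative families in the 16-model comparison space:

``noise_independent``
    Blame modulates decision noise additively, independent of uncertainty:
    ``log beta = beta0 - zeta*sigmahat2 + nu*pblame``.
``value``
    Blame enters as an (expected negative) value rather than a noise
    modulator: the subjective utility of a cue is its correct probability
    plus ``lam * p(wrong|cue) * pblame``, with a plain UDN temperature.
``none``
    No blame effect; UDN-only softmax.

Each family is crossed with the depth of the perceptual model (2- vs 3-level
HGF) and with how the blame belief is obtained (Rescorla-Wagner learning vs a
fixed belief), giving 4 x 2 x 2 = 16 candidate models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import expit

from .hgf import EXP_CLIP, BeliefTrajectory

if TYPE_CHECKING:  # pragma: no cover
    from .task import Session

__all__ = [
    "ResponseParams",
    "ModelSpec",
    "BLAME_EFFECTS",
    "enumerate_model_space",
    "cudn_spec",
    "inverse_temperature",
    "choice_probability",
    "session_loglik",
]

#: floor applied to per-trial choice probabilities inside the log-likelihood
PROB_FLOOR = 1e-12

BLAME_EFFECTS = ("none", "value", "noise_independent", "noise_interaction")


@dataclass(frozen=True)
class ResponseParams:
    """Free parameters of the response model.

    beta0
        Baseline log inverse temperature.
    zeta
        Degree of uncertainty-induced decision noise (>= 0).
    nu
        Degree of suppression of UDN as pblame increases (sign-free; a
        negative value amplifies UDN under blame).
    lam
        Blame-as-value weight; used only by the ``value`` family, where it is
        expected to be negative.
    """

    beta0: float = 0.0
    zeta: float = 0.0
    nu: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not (self.zeta >= 0):
            raise ValueError(f"zeta must be >= 0, got {self.zeta}")
        for name in ("beta0", "nu", "lam"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: blame-effect family x HGF depth x blame learning."""

    id: int
    blame_effect: str
    hgf_levels: int
    blame_learning: str

    def __post_init__(self) -> None:
        if self.blame_effect not in BLAME_EFFECTS:
            raise ValueError(f"unknown blame_effect {self.blame_effect!r}")
        if self.hgf_levels not in (2, 3):
            raise ValueError("hgf_levels must be 2 or 3")
        if self.blame_learning not in ("rw", "fixed"):
            raise ValueError("blame_learning must be 'rw' or 'fixed'")

    @property
    def name(self) -> str:
        return f"{self.blame_effect}_hgf{self.hgf_levels}_{self.blame_learning}"

    @property
    def is_cudn(self) -> bool:
        return (
            self.blame_effect == "noise_interaction"
            and self.hgf_levels == 3
            and self.blame_learning == "rw"
        )

    @property
    def uses_blame(self) -> bool:
        return self.blame_effect != "none"

    def free_params(self) -> tuple[str, ...]:
        """Names of the free parameters of this model, in canonical order.

        For ``blame_learning='fixed'`` the free blame parameter is the fixed
        belief ``p_blame0`` (the RW learning rate is pinned at zero); for
        ``'rw'`` it is the learning rate ``alpha_rw`` (initial belief pinned
        at 0.5).  Models without a blame effect carry no blame parameters at
        all, so the rw/fixed factor is inert for them (the factorial space
        still lists both variants).
        """
        names = ["beta0", "zeta"]
        if self.blame_effect in ("noise_independent", "noise_interaction"):
            names.append("nu")
        if self.blame_effect == "value":
            names.append("lam")
        if self.uses_blame:
            names.append("alpha_rw" if self.blame_learning == "rw" else "p_blame0")
        names.append("omega")
        if self.hgf_levels == 3:
            names.append("theta")
        return tuple(names)


def enumerate_model_space() -> list[ModelSpec]:
    """The 16 candidate models in deterministic order (ids 1..16)."""
    specs = []
    i = 1
    for effect in BLAME_EFFECTS:
        for levels in (2, 3):
            for learning in ("rw", "fixed"):
                specs.append(ModelSpec(i, effect, levels, learning))
                i += 1
    return specs


def cudn_spec() -> ModelSpec:
    """The CUDN model: interaction blame effect, 3-level HGF, RW blame learning."""
    (spec,) = [m for m in enumerate_model_space() if m.is_cudn]
    return spec


def inverse_temperature(
    uncertainty,
    pblame,
    params: ResponseParams,
    spec: ModelSpec,
):
    """Trial-wise softmax inverse temperature for one model family.

    ``uncertainty`` is the trial's decision uncertainty (see
    ``BeliefTrajectory.decision_uncertainty``).  Accepts scalars or arrays.
    The log inverse temperature is clipped at +/-``EXP_CLIP`` before
    exponentiation, so the result is always finite and strictly positive.
    """
    uncertainty = np.asarray(uncertainty, dtype=float)
    pblame = np.asarray(pblame, dtype=float)
    if not (np.all(np.isfinite(uncertainty)) and np.all(np.isfinite(pblame))):
        raise ValueError("non-finite inputs to inverse_temperature")
    if np.any(uncertainty <= 0):
        raise ValueError("uncertainty must be > 0")
    if np.any((pblame < 0) | (pblame > 1)):
        raise ValueError("pblame must lie in [0, 1]")

    with np.errstate(over="ignore"):  # extreme optimizer probes; clipped below
        if spec.blame_effect == "noise_interaction":
            log_beta = params.beta0 - (params.zeta - params.nu * pblame) * uncertainty
        elif spec.blame_effect == "noise_independent":
            log_beta = params.beta0 - params.zeta * uncertainty + params.nu * pblame
        else:  # value / none: plain UDN temperature
            log_beta = params.beta0 - params.zeta * uncertainty
    return np.exp(np.clip(log_beta, -EXP_CLIP, EXP_CLIP))


def choice_probability(values, beta, value_bias=0.0):
    """Softmax choice probabilities over the two cues.

    ``values`` is the pair (or pair of arrays) of subjective values of cue 1
    and cue 2; ``beta`` the inverse temperature; ``value_bias`` an additive
    logit-scale bias in favour of cue 1 (zero outside the value family, where
    blame-value terms are instead folded into the utilities).  Returns the
    pair ``(p1, p2)`` summing to one.
    """
    v1, v2 = values
    x = np.asarray(beta, dtype=float) * (np.asarray(v1, float) - np.asarray(v2, float))
    x = x + value_bias
    p1 = expit(x)
    return p1, 1.0 - p1


def _utilities(trajectory: BeliefTrajectory, params: ResponseParams, spec: ModelSpec):
    mh1 = trajectory.muhat1
    if spec.blame_effect == "value":
        pb = trajectory.pblame
        u1 = mh1 + params.lam * (1.0 - mh1) * pb
        u2 = (1.0 - mh1) + params.lam * mh1 * pb
        return u1, u2
    return mh1, 1.0 - mh1


def trial_choice_probabilities(
    trajectory: BeliefTrajectory,
    params: ResponseParams,
    spec: ModelSpec,
):
    """Per-trial probability of choosing cue 1 under the model (vectorized)."""
    beta = inverse_temperature(trajectory.decision_uncertainty, trajectory.pblame, params, spec)
    p1, _ = choice_probability(_utilities(trajectory, params, spec), beta)
    return p1


def session_loglik(
    session: "Session",
    trajectory: BeliefTrajectory,
    params: ResponseParams,
    spec: ModelSpec,
) -> float:
    """Log-likelihood of the observed choices given belief trajectories.

    Sums the log probability of the observed choice on every trial, with
    probabilities floored at ``PROB_FLOOR`` so the result is always finite.
    """
    if len(trajectory) != session.n_trials:
        raise ValueError(
            f"trajectory length {len(trajectory)} does not match "
            f"session length {session.n_trials}"
        )
    p1 = trial_choice_probabilities(trajectory, params, spec)
    p_obs = np.where(session.choice == 1, p1, 1.0 - p1)
    return float(np.sum(np.log(np.maximum(p_obs, PROB_FLOOR))))
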