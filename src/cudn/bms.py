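"""Random-effects Bayesian model selection (RFX-BMS) over log model evidences.

Given a subjects-by-models matrix of log model evidences, the model identity
of each subject is treated as a random effect drawn from population
frequencies ``r`` with a Dirichlet prior.  A variational fixed-point scheme
yields the Dirichlet posterior ``Dir(alpha)``; exceedance probabilities (EP,
the posterior probability that a model is the most frequent) are estimated by
Monte Carlo over Dirichlet draws; the Bayes omnibus risk (BOR) is the
posterior probability of the null model in which all frequencies are equal,
obtained from the variational free energies of the two hypotheses; and the
protected exceedance probability shrinks EP toward uniform by the BOR:

    PEP_m = EP_m * (1 - BOR) + BOR / K.

Free-energy expressions (at the converged variational solution, with
responsibilities ``u_nm`` and evidences ``L_nm``):

    F1 = sum_nm u_nm * (L_nm + psi(alpha_m) - psi(alpha_.))
         - sum_nm u_nm log u_nm - KL( Dir(alpha) || Dir(alpha0) )
    F0 = sum_n [ logsumexp_m(L_nm) - log K ]
    BOR = 1 / (1 + exp(F1 - F0))
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc, digamma, expit, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "vb_dirichlet",
    "exceedance_prob",
    "two_model_exceedance",
    "bayes_omnibus_risk",
    "protected_ep",
    "run_bms",
]


def _as_evidence_array(evidence) -> tuple[np.ndarray, list[str]]:
    """Accept a DataFrame (subjects x models) or 2-d array; return array + names."""
    if isinstance(evidence, pd.DataFrame):
        arr = evidence.to_numpy(dtype=float)
        names = [str(c) for c in evidence.columns]
    else:
        arr = np.asarray(evidence, dtype=float)
        names = [f"m{j + 1}" for j in range(arr.shape[1])] if arr.ndim == 2 else []
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("evidence must be a 2-d subjects x models matrix with >= 2 models")
    if not np.all(np.isfinite(arr)):
        raise ValueError("evidence matrix contains non-finite entries")
    return arr, names


@dataclass
class BMSResult:
    """Posterior summary of one RFX-BMS run."""

    model_names: list[str]
    alpha: np.ndarray   # Dirichlet concentrations
    r: np.ndarray       # expected model frequencies
    ep: np.ndarray      # exceedance probabilities
    bor: float          # Bayes omnibus risk
    pep: np.ndarray     # protected exceedance probabilities
    responsibilities: np.ndarray  # subjects x models posterior assignments

    @property
    def best_model(self) -> str:
        return self.model_names[int(np.argmax(self.pep))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"alpha": self.alpha, "r": self.r, "ep": self.ep, "pep": self.pep},
            index=pd.Index(self.model_names, name="model"),
        )


def vb_dirichlet(
    evidence,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variational Dirichlet posterior over model frequencies.

    Fixed-point iteration: subject responsibilities are softmax of
    ``L_nm + psi(alpha_m) - psi(sum alpha)``, and ``alpha = alpha0 + sum_n u_nm``.
    Returns ``(alpha, r, responsibilities)``.

    Raises ``RuntimeError`` (carrying the iteration trace) on non-convergence.
    """
    L, _ = _as_evidence_array(evidence)
    n, K = L.shape
    if alpha0 <= 0:
        raise ValueError("alpha0 must be > 0")
    alpha = np.full(K, alpha0 + n / K)
    trace = []
    for _ in range(max_iter):
        w = L + digamma(alpha) - digamma(alpha.sum())
        u = np.exp(w - logsumexp(w, axis=1, keepdims=True))
        alpha_new = alpha0 + u.sum(axis=0)
        step = float(np.max(np.abs(alpha_new - alpha)))
        trace.append(step)
        alpha = alpha_new
        if step < tol:
            r = alpha / alpha.sum()
            return alpha, r, u
    raise RuntimeError(
        f"vb_dirichlet did not converge in {max_iter} iterations; "
        f"last 5 step sizes: {trace[-5:]}"
    )


def exceedance_prob(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities under ``Dir(alpha)``.

    The EP of model m is the frequency with which its sampled population
    frequency is the maximum; exact ties are broken uniformly at random.
    Samples are drawn in chunks to bound memory.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    rng = np.random.default_rng(seed)
    K = len(alpha)
    counts = np.zeros(K)
    remaining = int(n_samples)
    chunk = 200_000
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.dirichlet(alpha, size=m)
        top = draws.max(axis=1, keepdims=True)
        ties = draws == top
        # uniform tie-break: random scores masked to the tied maxima
        winner = np.argmax(ties * rng.random(ties.shape), axis=1)
        counts += np.bincount(winner, minlength=K)
        remaining -= m
    return counts / n_samples


def two_model_exceedance(alpha: Sequence[float]) -> float:
    """Closed-form EP of model 1 for K=2: P(x > 1/2) under Beta(alpha1, alpha2)."""
    a1, a2 = alpha
    return float(1.0 - betainc(a1, a2, 0.5))


def _dirichlet_kl(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL( Dir(alpha) || Dir(alpha0) )."""
    a_sum = alpha.sum()
    return float(
        gammaln(a_sum)
        - gammaln(alpha).sum()
        - gammaln(alpha0.sum())
        + gammaln(alpha0).sum()
        + ((alpha - alpha0) * (digamma(alpha) - digamma(a_sum))).sum()
    )


def _free_energies(evidence, alpha0: float = 1.0) -> tuple[float, float]:
    """Variational free energies (F1 alternative, F0 null) for the BOR."""
    L, _ = _as_evidence_array(evidence)
    n, K = L.shape
    alpha, _, u = vb_dirichlet(L, alpha0=alpha0)
    a0 = np.full(K, alpha0)
    psi_term = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(u > 0, u * np.log(u), 0.0)
    f1 = float((u * (L + psi_term)).sum() - ent.sum() - _dirichlet_kl(alpha, a0))
    f0 = float(logsumexp(L, axis=1).sum() - n * np.log(K))
    return f1, f0


def bayes_omnibus_risk(evidence, alpha0: float = 1.0) -> float:
    """Posterior probability that all models are equally frequent (the null)."""
    f1, f0 = _free_energies(evidence, alpha0=alpha0)
    return float(expit(f0 - f1))


def protected_ep(ep: np.ndarray, bor: float) -> np.ndarray:
    """Protected exceedance probabilities: EP shrunk toward uniform by the BOR."""
    ep = np.asarray(ep, dtype=float)
    if not (0.0 <= bor <= 1.0):
        raise ValueError("bor must lie in [0, 1]")
    K = len(ep)
    return ep * (1.0 - bor) + bor / K


def run_bms(
    evidence,
    alpha0: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Full RFX-BMS: Dirichlet posterior, EP, BOR and protected EP."""
    L, names = _as_evidence_array(evidence)
    alpha, r, u = vb_dirichlet(L, alpha0=alpha0)
    ep = exceedance_prob(alpha, n_samples=n_samples, seed=seed)
    bor = bayes_omnibus_risk(L, alpha0=alpha0)
    pep = protected_ep(ep, bor)
    return BMSResult(names, alpha, r, ep, bor, pep, u)
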