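"""Per-subject MAP estimation and Laplace-approximate log model evidence.

Each candidate model's free parameters are estimated by maximizing the log
joint (choice log-likelihood plus Gaussian log-prior) in a transformed space
where every parameter is unbounded: positive parameters (zeta, theta) are
log-transformed, unit-interval parameters (alpha_rw, the fixed blame belief)
logit-transformed, and sign-free parameters (beta0, nu, lam, omega) enter
identically.  Optimization is multi-start quasi-Newton (L-BFGS-B with
numerical gradients); the first start is the prior mean, the rest are prior
draws.  The log model evidence is the Laplace approximation at the MAP,

    log p(y | m)  ~=  log p(y, theta_MAP | m) + (d/2) log(2 pi)
                      - (1/2) log det( -Hessian ),

with a BIC-based fallback (log-likelihood minus (d/2) log n) when the
negative Hessian is not positive-definite.

Default priors (transformed space): beta0 ~ N(0, 2); log zeta ~ N(0, 2);
nu ~ N(0, 2) (the susceptibility sweep covers the (mean 0, variance 1)
setting); lam ~ N(0, 2); logit alpha_rw ~ N(0, 1); logit p_blame0 ~ N(0, 1);
omega ~ N(-3, 4); log theta ~ N(-6, 4).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .hgf import HGFParams, ParameterPathologyError, RWParams, run_perceptual
from .response import ModelSpec, ResponseParams, enumerate_model_space, session_loglik
from .task import Session

__all__ = [
    "ParamDef",
    "PriorSpec",
    "FitResult",
    "FitError",
    "default_priors",
    "to_native",
    "to_transformed",
    "fit_map",
    "laplace_evidence",
    "fit_cohort",
    "prior_susceptibility",
]

HESSIAN_STEP = 1e-4
_BAD = 1e10  # objective value for pathological parameter regions


@dataclass(frozen=True)
class ParamDef:
    """Transform and Gaussian prior (in transformed space) for one free parameter."""

    name: str
    transform: str  # identity | log | logit
    prior_mean: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.transform not in ("identity", "log", "logit"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.prior_var <= 0:
            raise ValueError("prior_var must be > 0")


#: mapping parameter name -> ParamDef
PriorSpec = dict[str, ParamDef]

_DEFAULTS: tuple[ParamDef, ...] = (
    ParamDef("beta0", "identity", 0.0, 2.0),
    ParamDef("zeta", "log", 0.0, 2.0),
    ParamDef("nu", "identity", 0.0, 2.0),
    ParamDef("lam", "identity", 0.0, 2.0),
    ParamDef("alpha_rw", "logit", 0.0, 1.0),
    ParamDef("p_blame0", "logit", 0.0, 1.0),
    ParamDef("omega", "identity", -3.0, 4.0),
    ParamDef("theta", "log", -6.0, 4.0),
)


def default_priors(spec: ModelSpec) -> PriorSpec:
    """Default priors restricted to the free parameters of ``spec``."""
    table = {p.name: p for p in _DEFAULTS}
    return {name: table[name] for name in spec.free_params()}


def to_transformed(native: dict[str, float], priors: PriorSpec) -> np.ndarray:
    """Map native parameter values into the unbounded fitting space."""
    out = np.empty(len(priors))
    for i, (name, pdef) in enumerate(priors.items()):
        x = native[name]
        if pdef.transform == "identity":
            out[i] = x
        elif pdef.transform == "log":
            if x <= 0:
                raise ValueError(f"{name} must be > 0 for the log transform, got {x}")
            out[i] = math.log(x)
        else:
            if not (0.0 < x < 1.0):
                raise ValueError(f"{name} must lie in (0, 1) for the logit transform, got {x}")
            out[i] = float(logit(x))
    return out


def to_native(theta: np.ndarray, priors: PriorSpec) -> dict[str, float]:
    """Inverse of :func:`to_transformed`."""
    out: dict[str, float] = {}
    for i, (name, pdef) in enumerate(priors.items()):
        x = float(theta[i])
        if pdef.transform == "identity":
            out[name] = x
        elif pdef.transform == "log":
            out[name] = math.exp(min(x, 700.0))
        else:
            out[name] = float(expit(x))
    return out


def _log_prior(theta: np.ndarray, priors: PriorSpec) -> float:
    lp = 0.0
    for i, pdef in enumerate(priors.values()):
        d = theta[i] - pdef.prior_mean
        lp -= 0.5 * (d * d / pdef.prior_var + math.log(2.0 * math.pi * pdef.prior_var))
    return lp


def _model_components(native: dict[str, float], spec: ModelSpec):
    hgf_params = HGFParams(
        omega=native["omega"],
        theta=native.get("theta", 0.0) if spec.hgf_levels == 3 else 0.0,
    )
    if spec.uses_blame and spec.blame_learning == "rw":
        rw_params = RWParams(alpha=native["alpha_rw"], p0=0.5)
    elif spec.uses_blame:
        rw_params = RWParams(alpha=0.0, p0=native["p_blame0"])
    else:
        rw_params = RWParams(alpha=0.0, p0=0.5)
    response_params = ResponseParams(
        beta0=native["beta0"],
        zeta=native["zeta"],
        nu=native.get("nu", 0.0),
        lam=native.get("lam", 0.0),
    )
    return hgf_params, rw_params, response_params


def _make_objective(session: Session, spec: ModelSpec, priors: PriorSpec):
    """Negative log joint in transformed space, with trajectory caching.

    The belief trajectory depends only on the perceptual parameters (omega,
    theta, alpha_rw / p_blame0), so during finite-difference gradients most
    evaluations can reuse the cached trajectory.
    """
    perceptual_names = {"omega", "theta", "alpha_rw", "p_blame0"}
    cache: dict[tuple, object] = {}

    def neg_log_joint(theta: np.ndarray) -> float:
        native = to_native(theta, priors)
        try:
            hgf_params, rw_params, response_params = _model_components(native, spec)
            key = tuple(round(native[n], 15) for n in priors if n in perceptual_names)
            traj = cache.get(key)
            if traj is None:
                traj = run_perceptual(session, hgf_params, rw_params, levels=spec.hgf_levels)
                if len(cache) > 32:
                    cache.clear()
                cache[key] = traj
            ll = session_loglik(session, traj, response_params, spec)
        except (ParameterPathologyError, OverflowError, FloatingPointError):
            return _BAD
        lp = _log_prior(theta, priors)
        val = -(ll + lp)
        return val if math.isfinite(val) else _BAD

    return neg_log_joint


@dataclass
class FitResult:
    """MAP fit of one model to one subject."""

    subject_id: str
    model_id: int
    model_name: str
    params: dict[str, float]             # native space
    params_transformed: dict[str, float]
    log_joint: float                     # log-lik + log-prior at MAP
    loglik: float                        # log-likelihood at MAP
    log_evidence: float                  # Laplace (or BIC-fallback) approximation
    hessian: np.ndarray | None           # of the negative log joint, transformed space
    n_trials: int
    converged: bool
    used_bic_fallback: bool
    n_restarts: int
    optimizer_message: str


class FitError(RuntimeError):
    """All optimizer restarts failed; carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list[str]):
        super().__init__(message)
        self.diagnostics = diagnostics


def _numeric_hessian(fun: Callable[[np.ndarray], float], x: np.ndarray, step: float = HESSIAN_STEP) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = fun(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        fpp = fun(x + ei)
        fmm = fun(x - ei)
        H[i, i] = (fpp - 2.0 * f0 + fmm) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * step**2)
    return H


# Eigenvalue window for regularizing a finite-difference Hessian whose
# spectrum is corrupted by a nearby non-smooth boundary of the objective
# (pathology penalty or exponent clip): curvatures below the weakest prior
# precision or absurdly large are numerical artifacts.
HESS_EIG_FLOOR = 1e-2
HESS_EIG_CAP = 1e4


def laplace_evidence(fit: FitResult) -> float:
    """Laplace log model evidence from a stored fit.

    ``log p(y|m) ~= log_joint + (d/2) log 2 pi - 0.5 log det(H)`` where ``H``
    is the Hessian of the negative log joint at the MAP.  When ``H`` is not
    positive-definite (a finite-difference artifact near a non-smooth region
    of the objective), its eigenvalues are clipped into
    ``[HESS_EIG_FLOOR, HESS_EIG_CAP]`` and the Laplace formula is applied to
    the regularized spectrum, with a warning; a BIC-based evidence is the
    last resort if the spectrum cannot be computed.  For a model with no
    free parameters the evidence is the log-likelihood.
    """
    d = len(fit.params)
    if d == 0:
        return fit.loglik
    if fit.hessian is not None:
        sign, logdet = np.linalg.slogdet(fit.hessian)
        if sign > 0:
            return float(fit.log_joint + 0.5 * d * math.log(2.0 * math.pi) - 0.5 * logdet)
        try:
            eigs = np.linalg.eigvalsh(fit.hessian)
            eigs = np.clip(eigs, HESS_EIG_FLOOR, HESS_EIG_CAP)
            warnings.warn(
                f"non-positive-definite Hessian for {fit.model_name} / "
                f"{fit.subject_id}; using eigenvalue-regularized Laplace evidence",
                stacklevel=2,
            )
            return float(
                fit.log_joint
                + 0.5 * d * math.log(2.0 * math.pi)
                - 0.5 * float(np.sum(np.log(eigs)))
            )
        except np.linalg.LinAlgError:
            pass
    warnings.warn(
        f"unusable Hessian for {fit.model_name} / {fit.subject_id}; "
        "using BIC-based evidence",
        stacklevel=2,
    )
    return float(fit.loglik - 0.5 * d * math.log(fit.n_trials))


def fit_map(
    session: Session,
    spec: ModelSpec,
    priors: PriorSpec | None = None,
    n_restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Multi-start MAP fit of one model to one session, with Laplace evidence.

    Start 1 is the prior mean; subsequent starts are prior draws from a
    generator seeded by ``seed`` (deterministic).  The best converged restart
    is returned; if every restart fails a :class:`FitError` is raised.
    """
    if priors is None:
        priors = default_priors(spec)
    missing = set(spec.free_params()) - set(priors)
    if missing:
        raise ValueError(f"priors missing for free parameters: {sorted(missing)}")
    priors = {name: priors[name] for name in spec.free_params()}  # canonical order

    neg_log_joint = _make_objective(session, spec, priors)
    rng = np.random.default_rng(seed)
    means = np.array([p.prior_mean for p in priors.values()])
    sds = np.array([math.sqrt(p.prior_var) for p in priors.values()])

    best = None
    diagnostics: list[str] = []
    for r in range(max(1, n_restarts)):
        x0 = means if r == 0 else rng.normal(means, sds)
        res = minimize(neg_log_joint, x0, method="L-BFGS-B", options={"gtol": 1e-6, "maxiter": 500})
        diagnostics.append(f"restart {r}: fun={res.fun:.4f} success={res.success} {res.message}")
        if not math.isfinite(res.fun) or res.fun >= _BAD:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FitError(
            f"all {n_restarts} restarts failed for model {spec.name} on {session.subject_id}",
            diagnostics,
        )

    theta = best.x
    native = to_native(theta, priors)
    log_joint = -float(best.fun)
    loglik = log_joint - _log_prior(theta, priors)
    H = _numeric_hessian(neg_log_joint, theta)
    fit = FitResult(
        subject_id=session.subject_id,
        model_id=spec.id,
        model_name=spec.name,
        params=native,
        params_transformed=dict(zip(priors, map(float, theta))),
        log_joint=log_joint,
        loglik=float(loglik),
        log_evidence=float("nan"),
        hessian=H,
        n_trials=session.n_trials,
        converged=bool(best.success),
        used_bic_fallback=False,
        n_restarts=max(1, n_restarts),
        optimizer_message=str(best.message),
    )
    sign, _ = np.linalg.slogdet(H)
    fit.used_bic_fallback = not (sign > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit.log_evidence = laplace_evidence(fit)
    return fit


def fit_cohort(
    sessions: Sequence[Session],
    specs: Iterable[ModelSpec] | None = None,
    priors_by_model: dict[int, PriorSpec] | None = None,
    n_restarts: int = 8,
    seed: int = 0,
    progress: Callable[[str], None] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every model to every subject.

    Returns ``(evidence, fits)``: the subjects x models log-evidence matrix
    and a tidy table of MAP parameter estimates (one row per subject x model).
    Per-fit seeds are derived deterministically from ``seed``.
    """
    if specs is None:
        specs = enumerate_model_space()
    specs = list(specs)
    ev = pd.DataFrame(
        index=pd.Index([s.subject_id for s in sessions], name="subject_id"),
        columns=[m.name for m in specs],
        dtype=float,
    )
    rows = []
    for i, session in enumerate(sessions):
        for j, spec in enumerate(specs):
            priors = priors_by_model.get(spec.id) if priors_by_model else None
            fit = fit_map(
                session,
                spec,
                priors=priors,
                n_restarts=n_restarts,
                seed=(seed * 100003 + i * 131 + j) % (2**31 - 1),
            )
            ev.iloc[i, j] = fit.log_evidence
            rows.append(
                {
                    "subject_id": fit.subject_id,
                    "model": fit.model_name,
                    "model_id": fit.model_id,
                    "log_evidence": fit.log_evidence,
                    "loglik": fit.loglik,
                    "used_bic_fallback": fit.used_bic_fallback,
                    **fit.params,
                }
            )
            if progress is not None:
                progress(f"fit {session.subject_id} {spec.name}")
    return ev, pd.DataFrame(rows)


def prior_susceptibility(
    sessions: Sequence[Session],
    nu_prior_settings: Sequence[tuple[float, float]],
    specs: Iterable[ModelSpec] | None = None,
    base_evidence: pd.DataFrame | None = None,
    n_restarts: int = 4,
    seed: int = 0,
    n_samples: int = 100_000,
) -> pd.DataFrame:
    """Sensitivity of the model comparison to the prior on ``nu``.

    For each ``(mean, variance)`` setting, the models containing ``nu`` are
    refit under that prior (all other models keep their evidences, supplied
    via ``base_evidence`` or fitted once under default priors) and the
    RFX-BMS is rerun.  Returns one row per setting with each model's PEP,
    the winning model and the BOR.
    """
    from .bms import run_bms

    if len(nu_prior_settings) < 1:
        raise ValueError("need at least one prior setting")
    if specs is None:
        specs = enumerate_model_space()
    specs = list(specs)
    nu_specs = [m for m in specs if "nu" in m.free_params()]
    other_specs = [m for m in specs if "nu" not in m.free_params()]

    if base_evidence is None:
        base_evidence, _ = fit_cohort(
            sessions, other_specs, n_restarts=n_restarts, seed=seed
        )
    rows = []
    for mean, var in nu_prior_settings:
        priors_by_model = {}
        for m in nu_specs:
            pr = default_priors(m)
            pr["nu"] = ParamDef("nu", "identity", mean, var)
            priors_by_model[m.id] = pr
        ev_nu, _ = fit_cohort(
            sessions, nu_specs, priors_by_model=priors_by_model, n_restarts=n_restarts, seed=seed
        )
        ev = pd.concat([base_evidence[[m.name for m in other_specs]], ev_nu], axis=1)
        ev = ev[[m.name for m in specs]]  # canonical column order
        result = run_bms(ev, n_samples=n_samples, seed=seed)
        row = {"nu_prior_mean": mean, "nu_prior_var": var, "bor": result.bor,
               "best_model": result.best_model}
        row.update({f"pep_{name}": p for name, p in zip(result.model_names, result.pep)})
        rows.append(row)
    return pd.DataFrame(rows)
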