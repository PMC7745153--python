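"""Behavioural statistics: block contrasts, reversal curves, nu-performance
correlations and the mood analysis.

Definitions follow the experiment: the *good* choice at a trial is the cue
designed to have the higher correct probability in the current block; an
*accurate* choice is one that actually produced correct feedback.  The
headline contrasts compare per-subject means between high- and low-blame
blocks; the good-choice contrast is additionally computed on the first 10
trials after each correct-probability reversal, where estimation uncertainty
is highest.  No multiple-testing correction is applied across the headline
contrasts (they are reported individually).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hgf import BeliefTrajectory
from .task import Session, TaskSchedule

__all__ = [
    "BlockContrast",
    "label_trials",
    "good_choice_metrics",
    "cohort_metrics",
    "contrast_high_low",
    "reversal_curve",
    "nu_performance_correlation",
    "mood_analysis",
]

EARLY_WINDOW = 10


def label_trials(schedule: TaskSchedule) -> pd.DataFrame:
    """Per-trial analysis labels: blame condition and trials since reversal.

    ``trials_since_reversal`` restarts at 1 on the first trial of every
    correct-probability block (including the first block of the session).
    """
    n = schedule.n_trials
    tsr = np.empty(n, dtype=np.int64)
    count = 0
    for k in range(n):
        count = 1 if schedule.is_reversal_start[k] else count + 1
        tsr[k] = count
    return pd.DataFrame(
        {
            "trial": np.arange(1, n + 1),
            "blame": schedule.blame_block_label,
            "trials_since_reversal": tsr,
            "good_cue": schedule.good_cue,
            "mood_probe": schedule.mood_probe,
        }
    )


def good_choice_metrics(
    session: Session,
    labels: pd.DataFrame | None = None,
    window: int = EARLY_WINDOW,
) -> dict[str, float]:
    """Per-subject means by blame condition.

    Returns good-choice proportion, accuracy and mean RT in each blame
    condition, plus the early-window (first ``window`` trials after each
    reversal) good-choice and accuracy variants.  A condition with no
    qualifying trials yields NaN (flagged missing, excluded pairwise by the
    contrast).
    """
    if labels is None:
        labels = label_trials(session.schedule)
    if len(labels) != session.n_trials:
        raise ValueError("labels are not aligned with the session")
    good = (session.choice == labels["good_cue"].to_numpy()).astype(float)
    acc = session.correct.astype(float)
    early = labels["trials_since_reversal"].to_numpy() <= window

    out: dict[str, float] = {}
    for cond in ("high", "low"):
        m = (labels["blame"] == cond).to_numpy()
        me = m & early

        def cell(values: np.ndarray, mask: np.ndarray) -> float:
            return float(values[mask].mean()) if mask.any() else float("nan")

        out[f"good_choice_{cond}"] = cell(good, m)
        out[f"accuracy_{cond}"] = cell(acc, m)
        out[f"rt_{cond}"] = cell(session.rt, m)
        out[f"good_choice_early_{cond}"] = cell(good, me)
        out[f"accuracy_early_{cond}"] = cell(acc, me)
    out["good_choice_overall"] = float(good.mean())
    out["accuracy_overall"] = float(acc.mean())
    return out


def cohort_metrics(sessions: Sequence[Session], window: int = EARLY_WINDOW) -> pd.DataFrame:
    """Stack per-subject metrics into a table indexed by subject."""
    rows = [
        {"subject_id": s.subject_id, **good_choice_metrics(s, window=window)} for s in sessions
    ]
    return pd.DataFrame(rows).set_index("subject_id")


@dataclass
class BlockContrast:
    """High- vs low-blame contrast of one behavioural metric."""

    metric: str
    test: str             # 'paired_t' or 'wilcoxon'
    mean_high: float
    mean_low: float
    statistic: float
    p_value: float
    effect_size: float    # Cohen's d (paired_t) or matched-pairs rank-biserial r
    ci_low: float         # 95% CI of the mean (high - low) difference
    ci_high: float
    n: int


def contrast_high_low(
    metrics: pd.DataFrame,
    metric: str,
    test: str = "paired_t",
) -> BlockContrast:
    """Two-tailed paired comparison of ``metric`` between blame conditions.

    ``metrics`` is the per-subject table from :func:`cohort_metrics`; the
    columns ``{metric}_high`` and ``{metric}_low`` are compared.  Subjects
    with a missing value in either condition are excluded pairwise.
    """
    hi = metrics[f"{metric}_high"].to_numpy(dtype=float)
    lo = metrics[f"{metric}_low"].to_numpy(dtype=float)
    keep = ~(np.isnan(hi) | np.isnan(lo))
    hi, lo = hi[keep], lo[keep]
    n = len(hi)
    if n < 2:
        raise ValueError("need at least 2 subjects with complete high/low pairs")

    diff = hi - lo
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    se = sd_diff / np.sqrt(n) if sd_diff > 0 else 0.0
    tcrit = stats.t.ppf(0.975, n - 1)
    ci = (mean_diff - tcrit * se, mean_diff + tcrit * se)

    if test == "paired_t":
        if sd_diff == 0:
            statistic, p = 0.0, 1.0
        else:
            statistic, p = stats.ttest_rel(hi, lo)
        d = mean_diff / sd_diff if sd_diff > 0 else 0.0
        effect = float(d)
    elif test == "wilcoxon":
        if np.all(diff == 0):
            statistic, p, effect = 0.0, 1.0, 0.0
        else:
            res = stats.wilcoxon(hi, lo, zero_method="wilcox")
            statistic, p = res.statistic, res.pvalue
            nz = diff[diff != 0]
            n_eff = len(nz)
            # matched-pairs rank-biserial correlation from the signed-rank sum
            effect = float(1.0 - 4.0 * statistic / (n_eff * (n_eff + 1)))
            # W returned by scipy is min(W+, W-); recover the sign from the mean
            effect = abs(effect) * (1.0 if mean_diff >= 0 else -1.0)
    else:
        raise ValueError(f"unknown test {test!r}")

    return BlockContrast(
        metric=metric,
        test=test,
        mean_high=float(hi.mean()),
        mean_low=float(lo.mean()),
        statistic=float(statistic),
        p_value=float(p),
        effect_size=effect,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        n=n,
    )


def reversal_curve(
    sessions: Sequence[Session],
    horizon: int = 20,
    n_boot: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean good-choice trajectory vs trials since reversal, per blame condition.

    Subject means are computed first; the cohort mean and a bootstrap 95%
    band (resampling subjects) are reported per position, together with the
    number of subjects contributing (positions beyond the shortest blocks use
    fewer trials and possibly fewer subjects).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    # per-subject mean good choice at each (condition, position)
    per_subj: dict[str, np.ndarray] = {}
    for cond in ("high", "low"):
        mat = np.full((len(sessions), horizon), np.nan)
        for i, s in enumerate(sessions):
            labels = label_trials(s.schedule)
            good = (s.choice == labels["good_cue"].to_numpy()).astype(float)
            for t in range(1, horizon + 1):
                m = (
                    (labels["blame"] == cond)
                    & (labels["trials_since_reversal"] == t)
                ).to_numpy()
                if m.any():
                    mat[i, t - 1] = good[m].mean()
        per_subj[cond] = mat

    rows = []
    for cond in ("high", "low"):
        mat = per_subj[cond]
        for t in range(horizon):
            col = mat[:, t]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                rows.append(
                    {"blame": cond, "trials_since_reversal": t + 1, "mean": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "n_subjects": 0}
                )
                continue
            boots = np.array(
                [col[rng.integers(0, len(col), len(col))].mean() for _ in range(n_boot)]
            )
            rows.append(
                {
                    "blame": cond,
                    "trials_since_reversal": t + 1,
                    "mean": float(col.mean()),
                    "ci_low": float(np.quantile(boots, 0.025)),
                    "ci_high": float(np.quantile(boots, 0.975)),
                    "n_subjects": int(len(col)),
                }
            )
    return pd.DataFrame(rows)


def nu_performance_correlation(
    nu: pd.Series,
    metrics: pd.DataFrame,
    trim_sd: float = 2.0,
) -> pd.DataFrame:
    """Spearman correlation of the suppression parameter with performance gains.

    Correlates each subject's fitted ``nu`` with the high-minus-low blame
    enhancement of the early-window good-choice proportion and of overall
    accuracy.  Reported for the full sample and after excluding subjects
    whose ``nu`` or enhancement lies beyond ``trim_sd`` standard deviations
    from the mean (robustness rerun).
    """
    nu = nu.astype(float)
    if len(nu) < 5:
        raise ValueError("need at least 5 subjects")
    aligned = metrics.loc[nu.index]
    targets = {
        "good_choice_enhancement": (
            aligned["good_choice_early_high"] - aligned["good_choice_early_low"]
        ),
        "accuracy_enhancement": aligned["accuracy_high"] - aligned["accuracy_low"],
    }
    rows = []
    for name, diff in targets.items():
        diff = diff.astype(float)
        for sample in ("full", "trimmed"):
            x, y = nu.to_numpy(), diff.to_numpy()
            if sample == "trimmed":
                keep = np.ones(len(x), dtype=bool)
                for v in (x, y):
                    sd = v.std(ddof=1)
                    if sd > 0:
                        keep &= np.abs(v - v.mean()) <= trim_sd * sd
                x, y = x[keep], y[keep]
            if np.std(x) == 0 or np.std(y) == 0:
                rho, p, flagged = float("nan"), float("nan"), True
            else:
                rho, p = stats.spearmanr(x, y)
                flagged = False
            rows.append(
                {"target": name, "sample": sample, "rho": float(rho),
                 "p_value": float(p), "n": int(len(x)), "degenerate": flagged}
            )
    return pd.DataFrame(rows)


def mood_analysis(
    sessions: Sequence[Session],
    trajectories: Sequence[BeliefTrajectory],
) -> dict:
    """Group-level effect of the blame belief on mood ratings.

    Per subject, mood ratings at probe trials are regressed on the concurrent
    blame belief ``pblame`` with the recent correct rate (last 8 trials) as a
    covariate; the per-subject ``pblame`` coefficients are then tested against
    zero with a one-sample t-test.  Subjects with constant mood are excluded
    (logged via a warning); a subject with fewer probes than regressors is an
    error.
    """
    import statsmodels.api as sm

    coefs = []
    excluded = []
    for session, traj in zip(sessions, trajectories):
        probes = np.flatnonzero(session.schedule.mood_probe)
        if len(probes) < 3:
            raise ValueError(
                f"subject {session.subject_id}: too few mood probes ({len(probes)}) "
                "for a per-subject regression"
            )
        mood = session.mood[probes]
        pb = traj.pblame[probes]
        recent = np.array(
            [session.correct[max(0, k - 7) : k + 1].mean() for k in probes]
        )
        if np.all(mood == mood[0]):
            excluded.append(session.subject_id)
            continue
        X = sm.add_constant(np.column_stack([pb, recent]))
        res = sm.OLS(mood, X).fit()
        coefs.append(res.params[1])
    if excluded:
        warnings.warn(
            f"excluded subjects with constant mood: {excluded}", stacklevel=2
        )
    coefs = np.asarray(coefs)
    if len(coefs) < 2:
        raise ValueError("fewer than 2 subjects with usable mood data")
    t, p = stats.ttest_1samp(coefs, 0.0)
    return {
        "mean_coef": float(coefs.mean()),
        "t": float(t),
        "p_value": float(p),
        "n": int(len(coefs)),
        "excluded": excluded,
        "coefs": coefs,
    }
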