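"""Per-subject behavioral conflict models and the CSE score.

Reaction times and accuracies from the emotional-Stroop task are modelled
with multiple linear (RT) and logistic (accuracy) regressions on current
trial congruency, previous trial congruency, their interaction, and
current-trial emotional valence.  Estimates are standardized: the RT
outcome is z-scored and binary predictors are effect-coded ±0.5, so linear
coefficients read as condition differences in RT standard deviations.

The congruency-sequence-effect (CSE) score used downstream as a predictor
is the raw mean RT difference CI − II over accurate trials; conflict
adaptation makes it positive (II responses are faster than CI).  Error
trials and run-initial trials are excluded from RT analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidArgumentError,
)

__all__ = [
    "BehavioralFit",
    "fit_rt_model",
    "fit_accuracy_model",
    "cse_score",
    "group_onesample_t",
]

REGRESSORS = ("congruency", "prev_congruency", "interaction", "valence")


@dataclass(frozen=True)
class BehavioralFit:
    kind: str  # "linear-RT" | "logistic-accuracy"
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    stats: dict[str, float]   # t (linear) or z (logistic) per coefficient
    p_values: dict[str, float]
    n_trials: int
    status: str = "ok"        # "ok" | "separation"


def _design(trials: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Effect-coded (±0.5) predictors; excludes run-initial trials."""
    usable = trials[trials["prev_congruency"] != "none"].copy()
    cong = np.where(usable["congruency"] == "I", 0.5, -0.5)
    prev = np.where(usable["prev_congruency"] == "I", 0.5, -0.5)
    val = np.where(usable["valence"] == "fearful", 0.5, -0.5)
    X = np.column_stack([cong, prev, cong * prev, val])
    return X, usable


def _check_rank(X: np.ndarray) -> None:
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DegenerateDesignError(
            "behavioral design is rank deficient (e.g. one congruency level)")


def fit_rt_model(trials: pd.DataFrame, min_trials: int = 20) -> BehavioralFit:
    """OLS of z-scored RT on the standardized conflict regressors.

    Uses accurate, non-run-initial trials only.
    """
    X, usable = _design(trials)
    keep = (usable["accuracy"] == 1) & np.isfinite(usable["rt_ms"])
    X, usable = X[keep.to_numpy()], usable[keep]
    if len(usable) < min_trials:
        raise InsufficientDataError(
            f"only {len(usable)} usable trials, need {min_trials}")
    _check_rank(X)
    rt = usable["rt_ms"].to_numpy(float)
    sd = rt.std(ddof=1)
    if sd == 0:
        raise DegenerateDesignError("zero RT variance")
    y = (rt - rt.mean()) / sd
    res = sm.OLS(y, sm.add_constant(X)).fit()
    names = ("intercept",) + REGRESSORS
    return BehavioralFit(
        kind="linear-RT",
        coefficients=dict(zip(names, res.params)),
        standard_errors=dict(zip(names, res.bse)),
        stats=dict(zip(names, res.tvalues)),
        p_values=dict(zip(names, res.pvalues)),
        n_trials=len(usable))


def fit_accuracy_model(trials: pd.DataFrame) -> BehavioralFit:
    """Logistic regression of accuracy on the same regressor set.

    Complete separation is flagged (``status="separation"``) rather than
    raised, mirroring the infinite-estimate warning of IRLS fitters.
    """
    X, usable = _design(trials)
    y = usable["accuracy"].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise InsufficientDataError("accuracy has a single outcome class")
    _check_rank(X)
    names = ("intercept",) + REGRESSORS
    status = "ok"
    import warnings
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X)).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(np.abs(res.params) > 50):
            status = "separation"
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, sm.add_constant(X)).fit_regularized(
                disp=0, alpha=1e-6, maxiter=500)
        status = "separation"
    return BehavioralFit(
        kind="logistic-accuracy",
        coefficients=dict(zip(names, np.asarray(res.params))),
        standard_errors=dict(zip(names, np.asarray(getattr(res, "bse", np.full(5, np.nan))))),
        stats=dict(zip(names, np.asarray(getattr(res, "tvalues", np.full(5, np.nan))))),
        p_values=dict(zip(names, np.asarray(getattr(res, "pvalues", np.full(5, np.nan))))),
        n_trials=len(usable), status=status)


def cse_score(trials: pd.DataFrame) -> float:
    """Congruency-sequence effect in ms: mean RT(CI) − mean RT(II),
    accurate trials only."""
    ok = trials[(trials["accuracy"] == 1) & np.isfinite(trials["rt_ms"])]
    ci = ok.loc[ok["trial_type"] == "CI", "rt_ms"]
    ii = ok.loc[ok["trial_type"] == "II", "rt_ms"]
    if len(ci) == 0 or len(ii) == 0:
        raise InsufficientDataError("need accurate trials in both CI and II")
    return float(ci.mean() - ii.mean())


def group_onesample_t(values, tail: str = "two"):
    """One-sample t test of per-subject scalars against zero.

    ``tail="one"`` tests the one-sided alternative mean > 0.
    Returns ``(t, df, p)``.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InvalidArgumentError("need at least 3 values")
    if x.std(ddof=1) == 0:
        raise InvalidArgumentError("zero variance")
    if tail not in ("two", "one"):
        raise InvalidArgumentError("tail must be 'two' or 'one'")
    alternative = "two-sided" if tail == "two" else "greater"
    res = stats.ttest_1samp(x, 0.0, alternative=alternative)
    return float(res.statistic), int(len(x) - 1), float(res.pvalue)
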