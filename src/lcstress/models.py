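"""Model comparison for symptom-change prediction.

Three Gaussian linear models are compared: a *base* model containing only
the traditionally used clinical measures (baseline symptom score and
pre-trauma questionnaire), a *full* model adding the physiological markers
(LC upregulation response, pupil dilation distance, LC–amygdala coupling,
CSE), and an *optimal* sparse model found by stepwise deviance selection.
Goodness of fit is summarised by R², adjusted R², AIC and BIC; ROC curves
and AUC summarise how well a continuous score separates subjects with
high vs low symptom change (median split).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import InvalidArgumentError

__all__ = ["ModelFit", "RocResult", "fit_model", "stepwise_select", "roc_auc"]


@dataclass(frozen=True)
class ModelFit:
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    r2: float
    adj_r2: float
    aic: float
    bic: float
    n: int
    residuals: np.ndarray


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    label_rule: str


def fit_model(table: pd.DataFrame, outcome: str,
              terms: tuple[str, ...] | list[str]) -> ModelFit:
    """Gaussian linear model of ``outcome`` on ``terms`` (plus intercept).

    AIC/BIC use the Gaussian maximum-likelihood log-likelihood; adjusted
    R² = 1 − (1 − R²)(n − 1)/(n − k − 1).
    """
    terms = tuple(terms)
    missing = [t for t in terms if t not in table.columns]
    if missing:
        raise InvalidArgumentError(f"unknown terms {missing}")
    sub = table.dropna(subset=[outcome, *terms])
    y = sub[outcome].to_numpy(float)
    n, k = len(y), len(terms)
    if k >= n - 1:
        raise InvalidArgumentError("too many terms for the sample size")
    X = sm.add_constant(sub[list(terms)].to_numpy(float)) if k else \
        np.ones((n, 1))
    res = sm.OLS(y, X).fit()
    names = ("intercept",) + terms
    r2 = float(res.rsquared) if k else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return ModelFit(terms=terms,
                    coefficients=dict(zip(names, res.params)),
                    p_values=dict(zip(names, res.pvalues)),
                    r2=r2, adj_r2=float(adj),
                    aic=float(res.aic), bic=float(res.bic),
                    n=n, residuals=np.asarray(res.resid))


def _gaussian_deviance(table, outcome, terms) -> float:
    """n·log(RSS/n): Gaussian deviance up to an additive constant."""
    fit = fit_model(table, outcome, terms)
    rss = float(np.sum(fit.residuals ** 2))
    return fit.n * np.log(rss / fit.n)


def stepwise_select(table: pd.DataFrame, outcome: str,
                    candidates: tuple[str, ...] | list[str] | None = None,
                    threshold: float = 0.05) -> ModelFit:
    """Forward deviance-threshold selection with removal passes.

    Starting from the constant model, the candidate whose addition gives the
    smallest deviance-difference chi-squared p-value is added while that
    p-value is below ``threshold``; after each addition, included terms whose
    removal p-value exceeds the threshold are dropped.  Scan order is the
    column order of the table, making the procedure deterministic.
    """
    if candidates is None:
        candidates = tuple(c for c in table.columns if c != outcome)
    candidates = tuple(candidates)
    if len(candidates) < 2:
        raise InvalidArgumentError("need at least 2 candidate terms")

    def lr_p(small_terms, big_terms):
        dev_s = _gaussian_deviance(table, outcome, small_terms)
        dev_b = _gaussian_deviance(table, outcome, big_terms)
        df = len(big_terms) - len(small_terms)
        return float(stats.chi2.sf(max(dev_s - dev_b, 0.0), df))

    included: list[str] = []
    changed = True
    while changed:
        changed = False
        best_p, best_term = None, None
        for term in candidates:
            if term in included:
                continue
            p = lr_p(tuple(included), tuple(included) + (term,))
            if best_p is None or p < best_p:
                best_p, best_term = p, term
        if best_term is not None and best_p < threshold:
            included.append(best_term)
            changed = True
        # removal pass
        for term in list(included):
            rest = tuple(t for t in included if t != term)
            if lr_p(rest, tuple(included)) >= threshold:
                included.remove(term)
                changed = True
    return fit_model(table, outcome, tuple(included))


def roc_auc(scores, outcome, cutoff: float | None = None) -> RocResult:
    """ROC curve and AUC for separating high vs low symptom change.

    Labels: outcome above the cohort median (or an explicit ``cutoff``) is
    positive; at-or-below is negative.  AUC by trapezoid, which equals the
    probability of concordant ordering of a random cross-class pair
    (ties counted half).
    """
    s = np.asarray(scores, dtype=float)
    o = np.asarray(outcome, dtype=float)
    cut = float(np.median(o)) if cutoff is None else cutoff
    labels = (o > cut).astype(int)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos < 3 or n_neg < 3:
        raise InvalidArgumentError("need at least 3 subjects per class")
    fpr, tpr, thr = roc_curve(labels, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    rule = f"outcome > {'median' if cutoff is None else cutoff}"
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc, label_rule=rule)
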