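"""Symptom-change scoring and out-of-sample prediction of symptom change.

Change scores subtract the baseline (t0) questionnaire score from the two
mid-stressor assessments (t1, t2); their average is the prediction target.
Brain/pupil markers are associated with change via Spearman rank
correlation and robust (bisquare) regression, and compared between
median-split outcome groups with a pooled two-sample t test.

The headline procedure is leave-two-subjects-out (LTSO) pairwise
prediction: for every ordered pair of subjects (i, j) a linear model is fit
on the remaining N−2 subjects and used to predict both; the pair is scored
correct when the predicted ordering of their change scores matches the
observed one (ties score 0.5).  Accuracy is the percentage of correct pairs
over all N·(N−1) ordered pairs (2256 at N = 48); because the scoring rule
is symmetric in (i, j), this equals the unordered-pair accuracy.  A
permutation null repeats the whole procedure on shuffled change scores;
p = (1 + #{null ≥ observed}) / (1 + n_perm).

The per-pair model refits are computed exactly via rank-2 downdates of the
full-sample normal equations, which makes the 1000-permutation null cheap:
the pair-wise prediction operators depend only on the predictors and are
reused across permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations as iter_permutations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDesignError,
    InvalidArgumentError,
)

__all__ = [
    "SymptomPanel",
    "PredictionResult",
    "symptom_change",
    "spearman_rho",
    "robust_regression",
    "median_split_test",
    "loso_predict",
    "ltso_accuracy",
    "permutation_null",
]


@dataclass(frozen=True)
class PredictionResult:
    accuracy: float              # percent of pairs correctly ordered
    n_pairs: int                 # N·(N−1) ordered pairs
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None
    null_pct5: float | None = None
    null_pct95: float | None = None
    seed: int | None = None
    predictors: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# symptom panel

def symptom_change(panel: pd.DataFrame) -> pd.DataFrame:
    """Derive change scores from raw t0/t1/t2 questionnaire scores.

    For each instrument: Δt1 = t1 − t0, Δt2 = t2 − t0, mean change =
    (Δt1 + Δt2)/2.  Subjects missing any timepoint are excluded; the count
    is recorded in ``df.attrs["n_excluded"]``.
    """
    req = [f"{inst}_{t}" for inst in ("STAI", "PHQ") for t in ("t0", "t1", "t2")]
    missing = [c for c in req if c not in panel.columns]
    if missing:
        raise InvalidArgumentError(f"panel lacks columns {missing}")
    complete = panel.dropna(subset=req).copy()
    for inst in ("STAI", "PHQ"):
        complete[f"{inst}_d1"] = complete[f"{inst}_t1"] - complete[f"{inst}_t0"]
        complete[f"{inst}_d2"] = complete[f"{inst}_t2"] - complete[f"{inst}_t0"]
        complete[f"{inst}_mean_change"] = (
            complete[f"{inst}_d1"] + complete[f"{inst}_d2"]) / 2.0
    complete.attrs["n_excluded"] = len(panel) - len(complete)
    return complete


#: alias documenting the domain type: a panel with derived change scores
SymptomPanel = pd.DataFrame


# ---------------------------------------------------------------------------
# associations

def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties.

    p-value: exact permutation enumeration for n ≤ 9, otherwise the
    t-approximation ``t = rho·sqrt((n−2)/(1−rho²))`` on n−2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 5:
        raise InvalidArgumentError("need at least 5 observations")
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise InvalidArgumentError("zero rank variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        obs = abs(rho)
        count = total = 0
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = np.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
        for perm in iter_permutations(range(n)):
            r = float(rx_c[list(perm)] @ ry_c) / denom
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def robust_regression(x, y, max_iter: int = 200, tol: float = 1e-8):
    """IRLS robust line fit with Tukey bisquare weights (tuning 4.685).

    Returns ``(slope, intercept, slope_p, converged)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise InvalidArgumentError("need at least 5 observations")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("constant predictor")
    X = sm.add_constant(x)
    model = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=max_iter, tol=tol, conv="coefs")
    converged = bool(getattr(res, "converged", True))
    return (float(res.params[1]), float(res.params[0]),
            float(res.pvalues[1]), converged)


def median_split_test(predictor, outcome):
    """Compare the predictor between high/low outcome groups.

    Groups: outcome above the cohort median vs at-or-below (ties go to the
    lower group).  Pooled-variance two-sample t, df = n − 2.
    Returns ``(mean_high, mean_low, t, df, p)``.
    """
    pred = np.asarray(predictor, dtype=float)
    out = np.asarray(outcome, dtype=float)
    n = len(pred)
    if n < 6:
        raise InvalidArgumentError("need at least 6 subjects")
    med = np.median(out)
    high = pred[out > med]
    low = pred[out <= med]
    if len(high) < 2 or len(low) < 2:
        raise InvalidArgumentError("median split leaves a group of size < 2")
    if high.std(ddof=1) == 0 and low.std(ddof=1) == 0 \
            and high.mean() == low.mean():
        return (float(high.mean()), float(low.mean()), 0.0, int(n - 2), 1.0)
    res = stats.ttest_ind(high, low, equal_var=True)
    return (float(high.mean()), float(low.mean()), float(res.statistic),
            int(n - 2), float(res.pvalue))


# ---------------------------------------------------------------------------
# LOSO / LTSO prediction

def _design(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        names = tuple(X.columns)
        M = X.to_numpy(float)
    else:
        M = np.asarray(X, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        names = tuple(f"x{i}" for i in range(M.shape[1]))
    if not np.all(np.isfinite(M)):
        raise InvalidArgumentError("predictor table contains non-finite values")
    return np.column_stack([np.ones(len(M)), M]), names


def loso_predict(X, y):
    """Leave-one-subject-out linear prediction.

    For each subject the model is fit on the other N−1 and used to predict
    the held-out subject.  Returns ``(predictions, rho, p, excluded)`` where
    ``rho`` is the Spearman correlation between observed and predicted
    values over the non-excluded folds.
    """
    Xd, _ = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise InvalidArgumentError("need at least 10 subjects")
    preds = np.full(n, np.nan)
    excluded = []
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xi, yi = Xd[keep], y[keep]
        if np.linalg.matrix_rank(Xi) < Xi.shape[1]:
            excluded.append(i)
            continue
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        preds[i] = Xd[i] @ beta
    ok = np.isfinite(preds)
    rho, p = spearman_rho(y[ok], preds[ok])
    return preds, rho, p, excluded


def _pair_operators(Xd: np.ndarray):
    """Per-pair leave-two-out prediction operators.

    For every unordered pair (i, j) the leave-(i,j)-out least-squares fit is
    obtained from the full-sample inverse Gram by an exact rank-2 downdate;
    the predicted difference ŷ_i − ŷ_j is then the linear functional
    ``G[p]·y`` with ``G = D Xᵀ − a e_i − b e_j``, precomputable from the
    predictors alone.  Returns (i_idx, j_idx, G) with G shaped
    (n_pairs, n).
    """
    n, k = Xd.shape
    gram = Xd.T @ Xd
    try:
        A = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular full-sample design") from exc
    pairs = np.array(list(combinations(range(n), 2)))
    i_idx, j_idx = pairs[:, 0], pairs[:, 1]
    Xi, Xj = Xd[i_idx], Xd[j_idx]                     # (P, k)
    U = np.stack([Xi, Xj], axis=1)                    # (P, 2, k)
    AU = np.einsum("kl,pml->pmk", A, U)               # (P, 2, k) = U A
    S = np.eye(2)[None] - np.einsum("pml,pnl->pmn", U, AU)  # I − U A Uᵀ
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] * S[:, 1, 0]
    if np.any(np.abs(det) < 1e-12):
        raise DegenerateDesignError(
            "a leave-two-out fold has a singular design")
    Sinv = np.empty_like(S)
    Sinv[:, 0, 0] = S[:, 1, 1]
    Sinv[:, 1, 1] = S[:, 0, 0]
    Sinv[:, 0, 1] = -S[:, 0, 1]
    Sinv[:, 1, 0] = -S[:, 1, 0]
    Sinv /= det[:, None, None]
    # A_ij = A + (A Uᵀ) Sinv (U A);  d = (x_i − x_j) A_ij
    dx = Xi - Xj                                      # (P, k)
    dxA = dx @ A                                      # (P, k)
    corr = np.einsum("pm,pmn,pnk->pk",
                     np.einsum("pk,pmk->pm", dx, AU), Sinv, AU)
    D = dxA + corr                                    # (P, k)
    G = D @ Xd.T                                      # (P, n)
    a = np.einsum("pk,pk->p", D, Xi)
    b = np.einsum("pk,pk->p", D, Xj)
    P = len(pairs)
    G[np.arange(P), i_idx] -= a
    G[np.arange(P), j_idx] -= b
    return i_idx, j_idx, G


def _pair_accuracy(G, i_idx, j_idx, y) -> float:
    """Percent of pairs whose predicted ordering matches the observed one."""
    pred_diff = G @ y
    obs_diff = y[i_idx] - y[j_idx]
    sp, so = np.sign(pred_diff), np.sign(obs_diff)
    correct = np.where((sp == 0) | (so == 0), 0.5, (sp == so).astype(float))
    return float(100.0 * correct.mean())


def ltso_accuracy(X, y, predictors: tuple[str, ...] = ()) -> PredictionResult:
    """Leave-two-subjects-out pairwise prediction accuracy.

    Enumerates all N·(N−1) ordered left-out pairs; each fold refits the
    linear model on the remaining N−2 subjects (computed exactly via rank-2
    downdates) and predicts both left-out subjects.  Ties in predicted or
    observed differences score 0.5.
    """
    Xd, names = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise InvalidArgumentError("need at least 10 subjects")
    i_idx, j_idx, G = _pair_operators(Xd)
    acc = _pair_accuracy(G, i_idx, j_idx, y)
    return PredictionResult(accuracy=acc, n_pairs=n * (n - 1),
                            predictors=predictors or names)


def permutation_null(X, y, n_perm: int = 1000, seed: int | None = None,
                     per_pair_shuffle: bool = False,
                     predictors: tuple[str, ...] = ()) -> PredictionResult:
    """LTSO accuracy with a permutation null.

    Default scheme: one global shuffle of the change scores per permutation,
    reused across all folds of that permutation.  The literal per-pair
    variant (an independent shuffle for every left-out pair) is available
    via ``per_pair_shuffle=True``.
    """
    Xd, names = _design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 10:
        raise InvalidArgumentError("need at least 10 subjects")
    rng = np.random.default_rng(seed)
    i_idx, j_idx, G = _pair_operators(Xd)
    observed = _pair_accuracy(G, i_idx, j_idx, y)

    null = np.empty(n_perm)
    if per_pair_shuffle:
        P = len(i_idx)
        for p in range(n_perm):
            correct = np.empty(P)
            for q in range(P):
                yp = y[rng.permutation(n)]
                pd_ = float(G[q] @ yp)
                od = yp[i_idx[q]] - yp[j_idx[q]]
                sp, so = np.sign(pd_), np.sign(od)
                correct[q] = 0.5 if (sp == 0 or so == 0) else float(sp == so)
            null[p] = 100.0 * correct.mean()
    else:
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        Yp = y[perms]                              # (n_perm, n)
        pred_diff = Yp @ G.T                       # (n_perm, P)
        obs_diff = Yp[:, i_idx] - Yp[:, j_idx]
        sp, so = np.sign(pred_diff), np.sign(obs_diff)
        correct = np.where((sp == 0) | (so == 0), 0.5, (sp == so).astype(float))
        null = 100.0 * correct.mean(axis=1)

    p_value = float((1.0 + np.sum(null >= observed)) / (1.0 + n_perm))
    return PredictionResult(
        accuracy=observed, n_pairs=n * (n - 1), null_accuracies=null,
        p_value=p_value,
        null_pct5=float(np.percentile(null, 5)),
        null_pct95=float(np.percentile(null, 95)),
        seed=seed, predictors=predictors or names)
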