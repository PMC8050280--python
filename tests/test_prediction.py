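"""Symptom change scores, associations, LOSO/LTSO prediction machinery."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy import stats

from lcstress.errors import InvalidArgumentError
from lcstress.prediction import (
    loso_predict,
    ltso_accuracy,
    median_split_test,
    permutation_null,
    robust_regression,
    spearman_rho,
    symptom_change,
)


def brute_force_ltso(X, y):
    """Independent oracle: refit every ordered left-out pair from scratch."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, float)
    n = len(y)
    Xd = np.column_stack([np.ones(n), X])
    correct = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            keep = np.ones(n, bool)
            keep[[i, j]] = False
            beta, *_ = np.linalg.lstsq(Xd[keep], y[keep], rcond=None)
            sp = np.sign(Xd[i] @ beta - Xd[j] @ beta)
            so = np.sign(y[i] - y[j])
            correct.append(0.5 if (sp == 0 or so == 0) else float(sp == so))
    return 100.0 * np.mean(correct), len(correct)


class TestSymptomChange:
    def _panel(self, stai, phq):
        rows = []
        for s, (st, ph) in enumerate(zip(stai, phq), 1):
            rows.append({"subject": s,
                         "STAI_t0": st[0], "STAI_t1": st[1], "STAI_t2": st[2],
                         "PHQ_t0": ph[0], "PHQ_t1": ph[1], "PHQ_t2": ph[2]})
        return pd.DataFrame(rows)

    def test_arithmetic(self):
        p = self._panel([(10, 14, 12)], [(3, 3, 3)])
        out = symptom_change(p)
        assert out.loc[0, "STAI_d1"] == 4
        assert out.loc[0, "STAI_d2"] == 2
        assert out.loc[0, "STAI_mean_change"] == 3
        assert out.loc[0, "PHQ_mean_change"] == 0

    def test_missing_timepoint_excluded_with_report(self):
        p = self._panel([(10, 14, 12), (20, np.nan, 22)], [(3, 4, 5)] * 2)
        out = symptom_change(p)
        assert len(out) == 1
        assert out.attrs["n_excluded"] == 1


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x ** 3)[0] == pytest.approx(-1.0)

    def test_brute_force_formula(self, rng):
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        rho, _ = spearman_rho(x, y)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2 = np.sum((rx - ry) ** 2)
        assert abs(rho - (1 - 6 * d2 / (8 * 63))) < 1e-12

    def test_matches_scipy_for_larger_n(self, rng):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(InvalidArgumentError):
            spearman_rho(np.ones(6), np.arange(6.0))


class TestRobustRegression:
    def test_exact_line(self):
        x = np.linspace(0, 5, 20)
        slope, intercept, p, conv = robust_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0, abs=1e-8)
        assert intercept == pytest.approx(1.0, abs=1e-8)
        assert conv

    def test_resists_gross_outlier(self, rng):
        x = np.linspace(0, 10, 40)
        noise = 0.3 * rng.standard_normal(40)
        y = 1.5 * x + noise
        y_out = y.copy()
        y_out[7] += 30.0  # 10x residual sd
        slope_clean = np.polyfit(x, y, 1)[0]
        slope_rob, *_ = robust_regression(x, y_out)
        assert abs(slope_rob - slope_clean) / abs(slope_clean) < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(InvalidArgumentError):
            robust_regression(np.ones(10), np.arange(10.0))


class TestMedianSplit:
    def test_identical_predictor_gives_t_zero(self, rng):
        pred = np.full(20, 2.0)
        out = rng.standard_normal(20)
        mh, ml, t, df, p = median_split_test(pred, out)
        assert t == 0.0
        assert p == 1.0

    def test_df_matches_cohort_of_48(self, rng):
        pred = rng.standard_normal(48)
        out = rng.standard_normal(48)
        *_, df, _ = median_split_test(pred, out)
        assert df == 46

    def test_coupled_outcome_orders_groups(self, rng):
        hits = 0
        for s in range(300):
            pred = rng.standard_normal(48)
            out = pred + 0.5 * rng.standard_normal(48)
            mh, ml, t, df, p = median_split_test(pred, out)
            hits += mh > ml
        assert hits / 300 >= 0.99


class TestLoso:
    def test_exact_linear_relationship(self, rng):
        X = rng.standard_normal((16, 2))
        y = 1.0 + X @ [2.0, -1.0]
        preds, rho, p, excluded = loso_predict(X, y)
        assert np.allclose(preds, y, atol=1e-8)
        assert rho == pytest.approx(1.0)
        assert excluded == []

    def test_null_shows_no_spurious_skill(self, rng):
        """Independent outcome: LOSO rho must not indicate positive skill.

        Held-out linear predictions are anti-correlated with independent
        outcomes (the usual cross-validation artifact), so the null rho
        distribution sits below zero; spurious positive correlations beyond
        the chance band must be rare.
        """
        rhos = []
        for s in range(200):
            X = rng.standard_normal(24)
            y = rng.standard_normal(24)
            _, rho, _, _ = loso_predict(X, y)
            rhos.append(rho)
        rhos = np.asarray(rhos)
        assert np.mean(rhos) < 0.05
        assert np.mean(rhos > 0.4) <= 0.02

    def test_deterministic(self, rng):
        X = rng.standard_normal(12)
        y = rng.standard_normal(12)
        a = loso_predict(X, y)
        b = loso_predict(X, y)
        assert np.array_equal(a[0], b[0])


class TestLtso:
    def test_perfect_monotone_and_antimonotone(self):
        x = np.arange(12.0)
        assert ltso_accuracy(x, 3 * x + 2).accuracy == 100.0
        assert ltso_accuracy(x, -x).accuracy == 100.0  # model learns the sign
        assert ltso_accuracy(-x, x).accuracy == 100.0

    def test_pair_count_n48(self, rng):
        res = ltso_accuracy(rng.standard_normal(48), rng.standard_normal(48))
        assert res.n_pairs == 2256

    def test_matches_brute_force_oracle(self, rng):
        for k in (1, 3):
            X = rng.standard_normal((13, k))
            y = rng.standard_normal(13)
            fast = ltso_accuracy(X, y)
            slow, n_pairs = brute_force_ltso(X, y)
            assert fast.accuracy == pytest.approx(slow, abs=1e-9)
            assert fast.n_pairs == n_pairs

    def test_ordered_equals_unordered_scoring(self, rng):
        """The pairwise scoring rule is symmetric, so ordered-pair accuracy
        equals unordered-pair accuracy to machine precision."""
        X = rng.standard_normal(14)
        y = rng.standard_normal(14)
        n = 14
        Xd = np.column_stack([np.ones(n), X])
        scores = {}
        for i, j in combinations(range(n), 2):
            keep = np.ones(n, bool)
            keep[[i, j]] = False
            beta, *_ = np.linalg.lstsq(Xd[keep], y[keep], rcond=None)
            sp = np.sign(Xd[i] @ beta - Xd[j] @ beta)
            so = np.sign(y[i] - y[j])
            scores[(i, j)] = 0.5 if (sp == 0 or so == 0) else float(sp == so)
        unordered = 100.0 * np.mean(list(scores.values()))
        ordered, _ = brute_force_ltso(X, y)
        assert ordered == pytest.approx(unordered, abs=1e-12)
        assert ltso_accuracy(X, y).accuracy == pytest.approx(unordered, abs=1e-9)

    def test_rank_invariance_of_accuracy(self, rng):
        """Monotone transform of a single predictor changes accuracy < 2%."""
        for s in range(5):
            x = rng.standard_normal(30)
            y = 0.5 * x + rng.standard_normal(30)
            a1 = ltso_accuracy(x, y).accuracy
            a2 = ltso_accuracy(stats.rankdata(x), y).accuracy
            assert abs(a1 - a2) < 2.0

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(InvalidArgumentError):
            ltso_accuracy(rng.standard_normal(5), rng.standard_normal(5))


class TestPermutationNull:
    def test_p_value_floor(self, rng):
        x = np.arange(20.0)
        res = permutation_null(x, 2 * x, n_perm=99, seed=0)
        assert res.p_value >= 1.0 / 100
        assert res.p_value == pytest.approx(1.0 / 100)

    def test_identical_seed_identical_null(self, rng):
        x = rng.standard_normal(16)
        y = rng.standard_normal(16)
        a = permutation_null(x, y, n_perm=50, seed=9)
        b = permutation_null(x, y, n_perm=50, seed=9)
        assert np.array_equal(a.null_accuracies, b.null_accuracies)
        assert a.p_value == b.p_value

    def test_null_percentiles_ordered(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        res = permutation_null(x, y, n_perm=200, seed=3)
        assert res.null_pct5 <= res.null_pct95

    def test_global_and_per_pair_schemes_agree_on_strong_signal(self, rng):
        x = np.arange(16.0)
        y = x + 0.1 * rng.standard_normal(16)
        g = permutation_null(x, y, n_perm=60, seed=1)
        p = permutation_null(x, y, n_perm=60, seed=1, per_pair_shuffle=True)
        assert g.accuracy == p.accuracy  # observed statistic identical
        assert g.p_value < 0.05 and p.p_value < 0.05

    def test_zero_coupling_rarely_significant(self):
        """Cohorts with no LC–symptom coupling: p > 0.05 in ~95% of runs."""
        from lcstress.config import CohortConfig
        from lcstress.synthetic import simulate_symptoms
        cfg = CohortConfig(symptom_coupling_rho=0.0)
        rng = np.random.default_rng(17)
        sig = 0
        n_runs = 100
        for s in range(n_runs):
            amps = rng.standard_normal(48)
            panel = simulate_symptoms(amps, cfg, 5000 + s)
            y = ((panel["STAI_t1"] + panel["STAI_t2"]) / 2
                 - panel["STAI_t0"]).to_numpy(float)
            res = permutation_null(amps, y, n_perm=200,
                                   seed=int(rng.integers(2 ** 31)))
            sig += res.p_value < 0.05
        assert sig / n_runs < 0.12
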