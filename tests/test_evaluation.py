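"""Evaluation metrics: AUC rank statistic vs the exhaustive pairwise
oracle, PRESS/MSE/MSPE conventions, quintile odds ratios against the
cross-product ratio, and z-scoring."""

import numpy as np
import pytest

from ersmix.evaluation import (
    auc_rank,
    auc_with_tests,
    continuous_metrics,
    quintile_risk_stratification,
    standardize_ers,
)


def _auc_pairwise(y, s):
    """Exhaustive comparison oracle: P(s_case > s_control) + 0.5 P(tie)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAucRank:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_pairwise_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 31))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        # integer scores force ties
        s = rng.integers(0, 5, n).astype(float)
        assert auc_rank(y, s) == pytest.approx(_auc_pairwise(y, s), abs=1e-12)

    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc_rank(y, np.array([1.0, 2.0, 3.0, 4.0])) == 1.0
        assert auc_rank(y, np.array([4.0, 3.0, 2.0, 1.0])) == 0.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.standard_normal(2000)
        assert auc_rank(y, s) == pytest.approx(0.5, abs=0.03)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank(np.ones(5, dtype=int), np.arange(5.0))


class TestContinuousMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = continuous_metrics(y, y, None, y, y, None)
        assert m["train_corr"] == pytest.approx(1.0)
        assert m["mse"] == pytest.approx(0.0, abs=1e-20)
        assert m["mspe"] == pytest.approx(0.0, abs=1e-20)
        assert m["press"] == pytest.approx(0.0, abs=1e-20)

    def test_null_ers_correlation_small(self, rng):
        n = 4000
        y = rng.standard_normal(n)
        ers = rng.standard_normal(n)
        m = continuous_metrics(y, ers, None, y, ers, None)
        assert abs(m["test_corr"]) < 3.0 / np.sqrt(n)

    def test_press_matches_hand_oracle(self):
        y_tr = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ers_tr = np.array([0.9, 2.1, 2.9, 4.2, 5.1])
        y_te = np.array([1.5, 3.5, 2.5])
        ers_te = np.array([1.4, 3.6, 2.2])
        m = continuous_metrics(y_tr, ers_tr, None, y_te, ers_te, None)
        X = np.column_stack([np.ones(5), ers_tr])
        coef = np.linalg.lstsq(X, y_tr, rcond=None)[0]
        pred = np.column_stack([np.ones(3), ers_te]) @ coef
        assert m["press"] == pytest.approx(np.sum((y_te - pred) ** 2), abs=1e-12)
        assert m["mspe"] == pytest.approx(m["press"] / 3.0, abs=1e-12)

    def test_mspe_invariant_to_ers_shift(self, rng):
        y_tr, y_te = rng.standard_normal(100), rng.standard_normal(50)
        e_tr, e_te = rng.standard_normal(100), rng.standard_normal(50)
        m1 = continuous_metrics(y_tr, e_tr, None, y_te, e_te, None)
        m2 = continuous_metrics(y_tr, e_tr + 5.0, None, y_te, e_te + 5.0, None)
        assert m1["mspe"] == pytest.approx(m2["mspe"], abs=1e-10)

    def test_zero_variance_rejected(self, rng):
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="zero-variance"):
            continuous_metrics(y, np.ones(20), None, y, np.ones(20), None)


class TestAucWithTests:
    def test_permutation_p_in_valid_range(self, rng):
        n = 300
        z_tr = rng.standard_normal((n, 1))
        z_te = rng.standard_normal((n, 1))
        ers_tr = rng.standard_normal(n)
        ers_te = rng.standard_normal(n)
        y_tr = (z_tr[:, 0] + rng.logistic(0, 1, n) > 0).astype(int)
        y_te = (z_te[:, 0] + rng.logistic(0, 1, n) > 0).astype(int)
        out = auc_with_tests(y_tr, z_tr, ers_tr, y_te, z_te, ers_te,
                             n_perm=99, n_boot=100, seed=0)
        assert 1.0 / 100.0 <= out["perm_p"] <= 1.0
        assert 0.0 <= out["auc_base"] <= 1.0
        assert out["auc_base_ci"][0] <= out["auc_base"] <= out["auc_base_ci"][1]

    def test_informative_ers_improves_auc(self, rng):
        n = 1200
        liab_tr = rng.standard_normal(n)
        liab_te = rng.standard_normal(n)
        y_tr = (liab_tr + rng.logistic(0, 0.5, n) > 1.0).astype(int)
        y_te = (liab_te + rng.logistic(0, 0.5, n) > 1.0).astype(int)
        out = auc_with_tests(y_tr, None, liab_tr, y_te, None, liab_te,
                             n_perm=99, n_boot=100, seed=1)
        assert out["auc_full"] > out["auc_base"] + 0.1
        assert out["perm_p"] <= 0.05

    def test_single_class_test_rejected(self, rng):
        with pytest.raises(ValueError, match="single-class"):
            auc_with_tests(np.array([0, 1, 1, 0]), None, np.arange(4.0),
                           np.ones(4, dtype=int), None, np.arange(4.0),
                           n_perm=10, n_boot=10, seed=0)


class TestQuintiles:
    def test_cross_product_ratio_exact(self):
        # training scores 0..499 put the test scores squarely in Q1 / Q5
        ers_train = np.arange(500.0)
        ers_q1 = np.full(100, 10.0)
        ers_q5 = np.full(100, 480.0)
        y_q1 = np.r_[np.ones(10), np.zeros(90)].astype(int)
        y_q5 = np.r_[np.ones(30), np.zeros(70)].astype(int)
        out = quintile_risk_stratification(
            ers_train,
            np.r_[ers_q1, ers_q5],
            np.r_[y_q1, y_q5],
            Z_test=None,
        )
        assert out["or"] == pytest.approx((30 * 90) / (70 * 10), abs=1e-10)
        assert len(out["cutpoints"]) == 4

    def test_null_log_or_within_3se(self, rng):
        n = 2000
        ers_tr = rng.standard_normal(n)
        ers_te = rng.standard_normal(n)
        y_te = rng.integers(0, 2, n)
        out = quintile_risk_stratification(ers_tr, ers_te, y_te, Z_test=None)
        log_or = np.log(out["or"])
        se = (np.log(out["ci"][1]) - np.log(out["or"])) / 1.96
        assert abs(log_or) < 3.0 * se

    def test_adjusted_monotone_risk(self, rng):
        n = 3000
        ers_tr = rng.standard_normal(n)
        ers_te = rng.standard_normal(n)
        z = rng.standard_normal((n, 1))
        y_te = (0.8 * ers_te + z[:, 0] + rng.logistic(0, 1, n) > 0).astype(int)
        out = quintile_risk_stratification(ers_tr, ers_te, y_te, Z_test=z)
        assert out["or"] > 1.0
        assert out["ci"][0] > 1.0  # clearly positive risk gradient

    def test_too_few_distinct_values_rejected(self, rng):
        with pytest.raises(ValueError):
            quintile_risk_stratification(
                np.array([1.0, 1.0, 2.0, 2.0]), rng.standard_normal(10),
                np.ones(10, dtype=int),
            )


class TestStandardize:
    def test_self_reference(self, rng):
        z = standardize_ers(rng.standard_normal(100) * 3 + 2)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        assert np.allclose(standardize_ers(x), standardize_ers(3.0 * x - 7.0))

    def test_hand_case(self):
        ref = np.array([0.0, 4.0])  # mean 2, sd (ddof=1) = 2*sqrt(2)... use explicit
        out = standardize_ers(np.array([4.0]), reference=np.array([0.0, 2.0, 4.0, 2.0]))
        sd = np.std([0.0, 2.0, 4.0, 2.0], ddof=1)
        assert out[0] == pytest.approx((4.0 - 2.0) / sd)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            standardize_ers(np.ones(5))
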