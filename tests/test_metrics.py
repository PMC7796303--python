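"""Validation-metric suite against independent textbook-formula oracles."""

import numpy as np
import pytest
from scipy import stats

from sfqsar import (
    classification_metrics,
    cross_validate_regression,
    regression_metrics,
    rm2_metrics,
)


def oracle_rm2(y, yhat):
    """Second implementation of the external-validation formulas, written
    directly from their definitions with scipy/numpy primitives."""
    r, _ = stats.pearsonr(y, yhat)
    r2 = r**2
    k = float(y @ yhat / (yhat @ yhat))
    kp = float(y @ yhat / (y @ y))
    r0 = 1 - np.sum((y - k * yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    r0p = 1 - np.sum((yhat - kp * y) ** 2) / np.sum((yhat - yhat.mean()) ** 2)
    rm2 = r2 * (1 - np.sqrt(abs(r2 - r0)))
    rm2r = r2 * (1 - np.sqrt(abs(r2 - r0p)))
    n = len(y)
    sy2 = np.mean((y - y.mean()) ** 2)
    syh2 = np.mean((yhat - yhat.mean()) ** 2)
    cov = np.mean((y - y.mean()) * (yhat - yhat.mean()))
    ccc = 2 * cov / (sy2 + syh2 + (y.mean() - yhat.mean()) ** 2)
    f = (n - 2) * r2 / (1 - r2)
    return {"r2": r2, "r2m": rm2, "r2m_rev": rm2r,
            "r2m_avg": (rm2 + rm2r) / 2, "r2m_delta": abs(rm2 - rm2r),
            "k": k, "k_prime": kp, "ccc": ccc, "f_stat": f}


class TestClassificationMetrics:
    def test_perfect(self):
        y = np.array([0, 1, 0, 1, 1])
        rep = classification_metrics(y, y)
        assert rep["accuracy"] == rep["sensitivity"] == rep["specificity"] == 1.0

    def test_confusion_example(self):
        # TP=3 FN=1 TN=4 FP=2
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        yhat = np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1])
        rep = classification_metrics(y, yhat)
        assert rep["sensitivity"] == pytest.approx(0.75)
        assert rep["specificity"] == pytest.approx(2 / 3)
        assert rep["accuracy"] == pytest.approx(0.7)

    def test_total_inversion(self):
        y = np.array([0, 1, 0, 1])
        rep = classification_metrics(y, 1 - y)
        assert rep["accuracy"] == rep["sensitivity"] == rep["specificity"] == 0.0

    def test_single_class_gives_nan_not_zero(self):
        rep = classification_metrics(np.ones(4, dtype=int),
                                     np.ones(4, dtype=int))
        assert rep["sensitivity"] == 1.0
        assert np.isnan(rep["specificity"])


class TestRegressionMetrics:
    def test_perfect(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = regression_metrics(y, y)
        assert rep["r2"] == 1.0 and rep["rmse"] == 0.0 and rep["mae"] == 0.0

    def test_hand_example(self):
        rep = regression_metrics(np.array([0.0, 1, 2]), np.array([0.0, 1, 3]))
        assert rep["mae"] == pytest.approx(1 / 3)
        assert rep["rmse"] == pytest.approx(np.sqrt(1 / 3))
        assert rep["r2"] == pytest.approx(0.5)

    def test_mean_predictor_zero_r2(self):
        y = np.array([1.0, 2, 3, 4])
        rep = regression_metrics(y, np.full(4, y.mean()))
        assert rep["r2"] == pytest.approx(0.0)

    def test_constant_y_raises(self):
        with pytest.raises(ValueError):
            regression_metrics(np.ones(5), np.arange(5.0))

    def test_rmse_dominates_mae(self, rng):
        for _ in range(200):
            n = rng.integers(3, 40)
            y = rng.standard_normal(n)
            yhat = y + rng.standard_normal(n)
            rep = regression_metrics(y, yhat)
            assert rep["rmse"] >= rep["mae"] - 1e-12

    def test_rss_tss_summation_oracle(self, rng):
        y = rng.standard_normal(30)
        yhat = y + 0.3 * rng.standard_normal(30)
        rss = sum((a - b) ** 2 for a, b in zip(y, yhat))
        tss = sum((a - y.mean()) ** 2 for a in y)
        assert regression_metrics(y, yhat)["r2"] == pytest.approx(1 - rss / tss)


class TestRm2Metrics:
    def test_perfect_concordance(self):
        y = np.array([1.0, 2, 3, 4])
        rep = rm2_metrics(y, y)
        assert rep["r2m"] == pytest.approx(1.0)
        assert rep["r2m_delta"] == pytest.approx(0.0)
        assert rep["k"] == rep["k_prime"] == pytest.approx(1.0)
        assert rep["ccc"] == pytest.approx(1.0)

    def test_constant_shift_breaks_concordance(self):
        y = np.array([0.0, 1, 2])
        rep = rm2_metrics(y, y + 1)
        assert rep["r2"] == pytest.approx(1.0)  # Pearson unaffected
        assert rep["ccc"] < 1.0
        assert rep["ccc"] == pytest.approx(oracle_rm2(y, y + 1)["ccc"])

    def test_printed_example_matches_oracle(self):
        y = np.array([1.0, 2, 3, 4])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        rep = rm2_metrics(y, yhat)
        ora = oracle_rm2(y, yhat)
        for name, val in ora.items():
            assert rep[name] == pytest.approx(val, abs=1e-6), name

    def test_oracle_equivalence_random(self, rng):
        for _ in range(300):
            n = int(rng.integers(4, 50))
            y = rng.standard_normal(n) * rng.uniform(0.5, 3)
            yhat = y * rng.uniform(0.3, 1.5) + rng.standard_normal(n) * 0.5
            rep = rm2_metrics(y, yhat)
            ora = oracle_rm2(y, yhat)
            for name, val in ora.items():
                assert rep[name] == pytest.approx(val, abs=1e-6), name

    def test_ccc_bounded_by_pearson(self, rng):
        for _ in range(500):
            n = int(rng.integers(3, 30))
            y = rng.standard_normal(n)
            yhat = rng.standard_normal(n)
            if np.var(y) == 0 or np.var(yhat) == 0:
                continue
            rep = rm2_metrics(y, yhat)
            r = abs(np.corrcoef(y, yhat)[0, 1])
            assert rep["ccc"] <= r + 1e-12

    def test_delta_nonnegative_and_rm2_below_r2(self, rng):
        for _ in range(200):
            y = rng.standard_normal(15)
            yhat = y + 0.4 * rng.standard_normal(15)
            rep = rm2_metrics(y, yhat)
            assert rep["r2m_delta"] >= 0
            assert rep["r2m"] <= rep["r2"] + 1e-12

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            rm2_metrics(np.ones(5), np.arange(5.0))


class TestCrossValidation:
    @staticmethod
    def _ols_fit(x, y, seed):
        coef, *_ = np.linalg.lstsq(
            np.column_stack([x, np.ones(len(x))]), y, rcond=None
        )
        return coef

    @staticmethod
    def _ols_predict(coef, x):
        return np.column_stack([x, np.ones(len(x))]) @ coef

    def test_noise_free_linear_near_perfect(self, rng):
        x = rng.standard_normal((60, 4))
        y = x @ np.array([1.0, -1, 2, 0.5])
        rep = cross_validate_regression(self._ols_fit, self._ols_predict,
                                        x, y, k=10, seed=0)
        assert rep["r2"] >= 0.95

    def test_loo_boundary(self, rng):
        x = rng.standard_normal((12, 2))
        y = x @ np.array([1.0, 2.0]) + 0.1 * rng.standard_normal(12)
        rep = cross_validate_regression(self._ols_fit, self._ols_predict,
                                        x, y, k=12, seed=0)
        assert np.isfinite(rep["r2"])

    def test_seeded_folds_reproducible(self, rng):
        x = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        a = cross_validate_regression(self._ols_fit, self._ols_predict,
                                      x, y, k=5, seed=4)
        b = cross_validate_regression(self._ols_fit, self._ols_predict,
                                      x, y, k=5, seed=4)
        assert a.metrics == b.metrics

    def test_too_many_folds(self, rng):
        with pytest.raises(ValueError):
            cross_validate_regression(self._ols_fit, self._ols_predict,
                                      rng.standard_normal((5, 2)),
                                      rng.standard_normal(5), k=6, seed=0)
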