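"""Validation metrics for the classification and regression models.

Covers the full external-validation suite: accuracy / sensitivity /
specificity for the classifier; r² (1 − RSS/TSS), RMSE and MAE for the
regressors; and the r²m family with through-origin slopes k and k′,
Lin's concordance correlation coefficient (CCC) and the one-predictor
regression F statistic.

The r²m scheme (Roy et al.) penalizes divergence between the ordinary
squared correlation r² of observed vs predicted and the corresponding
through-origin determination coefficients:

    k   = Σ y·ŷ / Σ ŷ²          (slope of y on ŷ through the origin)
    k′  = Σ y·ŷ / Σ y²
    r0² = 1 − Σ(y − k·ŷ)² / Σ(y − ȳ)²
    r0′² = 1 − Σ(ŷ − k′·y)² / Σ(ŷ − ŷ̄)²
    r²m = r²·(1 − √|r² − r0²|),   reverse r²m′ analogously,
    r²m(avg) = (r²m + r²m′)/2,    Δr²m = |r²m − r²m′|
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MetricsReport:
    metrics: dict[str, float]
    n_used: int
    coverage: float = 1.0
    subset: str | None = None

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def to_row(self) -> dict[str, float]:
        row = dict(self.metrics)
        row["n_used"] = self.n_used
        row["coverage"] = self.coverage
        return row


def classification_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """Accuracy, sensitivity (true positive rate) and specificity.

    If a class is absent from ``y`` the corresponding rate is undefined and
    reported as NaN rather than zero.
    """
    y = np.asarray(y, dtype=int)
    yhat = np.asarray(yhat, dtype=int)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    tp = int(np.sum((y == 1) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    n = len(y)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return MetricsReport(
        metrics={
            "accuracy": (tp + tn) / n,
            "sensitivity": sens,
            "specificity": spec,
        },
        n_used=n,
    )


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """r² = 1 − RSS/TSS, root-mean-square error and mean absolute error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need at least two observations")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("constant observed values: r2 undefined")
    rss = float(np.sum((y - yhat) ** 2))
    resid = np.abs(y - yhat)
    return MetricsReport(
        metrics={
            "r2": 1.0 - rss / tss,
            "rmse": float(np.sqrt(np.mean((y - yhat) ** 2))),
            "mae": float(np.mean(resid)),
        },
        n_used=len(y),
    )


def _pearson_r2(y: np.ndarray, yhat: np.ndarray) -> float:
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def rm2_metrics(y: np.ndarray, yhat: np.ndarray) -> MetricsReport:
    """The r²m family, k, k′, CCC and F for external validation."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    n = len(y)
    if n < 3:
        raise ValueError("need at least three observations")
    if np.var(y) == 0 or np.var(yhat) == 0:
        raise ValueError("zero variance input")

    r2 = _pearson_r2(y, yhat)
    k = float(np.sum(y * yhat) / np.sum(yhat**2))
    k_prime = float(np.sum(y * yhat) / np.sum(y**2))
    r0_2 = 1.0 - float(np.sum((y - k * yhat) ** 2) / np.sum((y - y.mean()) ** 2))
    r0p_2 = 1.0 - float(
        np.sum((yhat - k_prime * y) ** 2) / np.sum((yhat - yhat.mean()) ** 2)
    )
    rm2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
    rm2_rev = r2 * (1.0 - np.sqrt(abs(r2 - r0p_2)))

    # Lin's concordance correlation (biased 1/n moments)
    sy, syh = np.var(y), np.var(yhat)
    cov = float(np.mean((y - y.mean()) * (yhat - yhat.mean())))
    ccc = 2 * cov / (sy + syh + (y.mean() - yhat.mean()) ** 2)

    f_stat = (n - 2) * r2 / (1 - r2) if r2 < 1 else float("inf")
    return MetricsReport(
        metrics={
            "r2": r2,
            "r2m": float(rm2),
            "r2m_rev": float(rm2_rev),
            "r2m_avg": float((rm2 + rm2_rev) / 2),
            "r2m_delta": float(abs(rm2 - rm2_rev)),
            "k": k,
            "k_prime": k_prime,
            "ccc": float(ccc),
            "f_stat": float(f_stat),
        },
        n_used=n,
    )


def cross_validate_regression(
    fit_fn,
    predict_fn,
    matrix_values: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
) -> MetricsReport:
    """k-fold cross-validated regression metrics on pooled held-out folds.

    ``fit_fn(x_train, y_train, fold_seed) -> model`` and
    ``predict_fn(model, x) -> ŷ`` abstract the learner so the same routine
    serves the MLP and any baseline.
    """
    x = np.asarray(matrix_values, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError("more folds than observations")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    pooled = np.empty(n)
    for i, fold in enumerate(folds):
        train = np.setdiff1d(perm, fold)
        model = fit_fn(x[train], y[train], seed + i)
        pooled[fold] = np.asarray(predict_fn(model, x[fold])).ravel()
    return regression_metrics(y, pooled)
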