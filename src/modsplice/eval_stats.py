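"""Benchmark metrics and basic-bootstrap model comparison.

Model comparisons resample the paired test items with replacement
(B = 999 by default), recompute the metric difference per resample,
and report the one-sided P value P = (1 + #{d* <= 0}) / (B + 1).
Confidence intervals use the percentile bootstrap (B = 1000, the 2.5th
and 97.5th percentiles of the resampled statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

METRIC_KINDS = ("pearson_r", "rmse", "auPR", "auROC")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValueError("zero-variance input for Pearson correlation")
    return float((xc * yc).sum() / denom)


def trapezoid_aupr(precision: Sequence[float], recall: Sequence[float]) -> float:
    """Trapezoidal area under a precision-recall curve.

    Points must be ordered by increasing recall.
    """
    recall = np.asarray(recall, dtype=np.float64)
    precision = np.asarray(precision, dtype=np.float64)
    if np.any(np.diff(recall) < 0):
        raise ValueError("recall must be non-decreasing")
    return float(np.trapezoid(precision, recall))


def metric(kind: str, observed, predicted) -> float:
    """A scalar performance metric.

    pearson_r and rmse for continuous responses; auROC and trapezoidal
    auPR for binary labels scored by a continuous prediction.
    """
    observed = np.asarray(observed, dtype=np.float64)
    predicted = np.asarray(predicted, dtype=np.float64)
    if observed.size != predicted.size:
        raise ValueError("observed/predicted length mismatch")
    if observed.size < 2:
        raise ValueError("need at least two observations")
    if kind == "pearson_r":
        return _pearson(observed, predicted)
    if kind == "rmse":
        return float(np.sqrt(np.mean((observed - predicted) ** 2)))
    if kind in ("auPR", "auROC"):
        classes = np.unique(observed)
        if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
            raise ValueError("binary observed labels with both classes required")
        if kind == "auROC":
            from sklearn.metrics import roc_auc_score

            return float(roc_auc_score(observed.astype(int), predicted))
        from sklearn.metrics import precision_recall_curve

        precision, recall, _ = precision_recall_curve(observed.astype(int), predicted)
        # sklearn returns decreasing recall ending at (recall 0, precision 1)
        return trapezoid_aupr(precision[::-1], recall[::-1])
    raise ValueError(f"unknown metric kind {kind!r}")


def bootstrap_p(d_star: np.ndarray) -> float:
    """One-sided basic-bootstrap P value from resampled differences.

    P = (1 + #{d*_i <= 0}) / (B + 1); its smallest attainable value is
    1 / (B + 1).
    """
    d = np.asarray(d_star, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty bootstrap difference vector")
    return float((1 + np.sum(d <= 0)) / (d.size + 1))


@dataclass
class ComparisonResult:
    metric_kind: str
    t1: float
    t2: float
    p_value: float
    b: int
    n_redrawn: int
    d_star: np.ndarray

    def summary(self) -> str:
        return (
            f"{self.metric_kind}: model1 = {self.t1:.4f}, model2 = {self.t2:.4f}, "
            f"one-sided bootstrap P = {self.p_value:.4g} (B = {self.b})"
        )


def compare_models(
    observed,
    predicted1,
    predicted2,
    metric_kind: str = "pearson_r",
    b: int = 999,
    seed: int = 0,
) -> ComparisonResult:
    """Basic-bootstrap comparison of two models on paired test items.

    Items (observation plus both predictions) are resampled together
    with replacement ``b`` times; resamples on which the metric is
    undefined (for instance a single-class draw for auROC) are redrawn
    and counted.
    """
    observed = np.asarray(observed, dtype=np.float64)
    p1 = np.asarray(predicted1, dtype=np.float64)
    p2 = np.asarray(predicted2, dtype=np.float64)
    if not (observed.size == p1.size == p2.size):
        raise ValueError("aligned observed and prediction vectors required")
    n = observed.size
    t1 = metric(metric_kind, observed, p1)
    t2 = metric(metric_kind, observed, p2)
    rng = np.random.default_rng(seed)
    d_star = np.empty(b)
    redrawn = 0
    i = 0
    while i < b:
        idx = rng.integers(0, n, size=n)
        try:
            d_star[i] = metric(metric_kind, observed[idx], p1[idx]) - metric(
                metric_kind, observed[idx], p2[idx]
            )
        except ValueError:
            redrawn += 1
            if redrawn > 100 * b:
                raise ValueError("metric undefined on almost all resamples")
            continue
        i += 1
    return ComparisonResult(
        metric_kind=metric_kind,
        t1=t1,
        t2=t2,
        p_value=bootstrap_p(d_star),
        b=b,
        n_redrawn=redrawn,
        d_star=d_star,
    )


def percentile_ci(
    values,
    statistic: Callable[[np.ndarray], float],
    b: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval of a statistic.

    ``b`` resamples of the data (with replacement, same size) are drawn
    and the interval is the pair of (1-level)/2 and 1-(1-level)/2
    percentiles of the resampled statistic, with linear interpolation
    between closest ranks.
    """
    values = np.asarray(values)
    if values.shape[0] < 2:
        raise ValueError("need at least two observations")
    rng = np.random.default_rng(seed)
    thetas = np.empty(b)
    i = 0
    redrawn = 0
    while i < b:
        idx = rng.integers(0, values.shape[0], size=values.shape[0])
        try:
            thetas[i] = statistic(values[idx])
        except ValueError:
            redrawn += 1
            if redrawn > 100 * b:
                raise ValueError("statistic undefined on almost all resamples")
            continue
        i += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(thetas, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
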