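"""Evaluation metrics with patient-resampled bootstrap confidence intervals.

Regression: MAE, coefficient of determination R^2 (about the test mean, may
be negative), Pearson r, the baseline MAE of always predicting the test
mean, and the percentage error reduction against that baseline.
Classification: AUC on patient-level scores, where a patient's score is the
maximum over all of that patient's image scores (referral on the worse eye)
and the patient label is positive if any image is. 95% CIs are percentile
intervals over seeded bootstrap resamples drawn at the patient level —
images of one patient are dependent, so the patient is the exchangeable
unit — 5000 iterations by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mean_absolute_error, r2_score, roc_auc_score


def regression_metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> tuple[float, float, float]:
    """(MAE, R^2, Pearson r). R^2 = 1 - SS_res/SS_tot about the true mean."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) < 2:
        raise ValueError("y_true and y_pred must be equal-length 1-D arrays with n >= 2")
    if np.var(y_true) == 0:
        raise ValueError("R^2 and Pearson r are undefined for zero-variance y_true")
    mae = float(mean_absolute_error(y_true, y_pred))
    r2 = float(r2_score(y_true, y_pred))
    if np.var(y_pred) == 0:
        r = 0.0  # constant predictions carry no linear association
    else:
        r = float(stats.pearsonr(y_true, y_pred).statistic)
    return mae, r2, r


def baseline_mae(y_test: Sequence[float]) -> float:
    """Mean absolute deviation about the test mean (error of the mean predictor)."""
    y = np.asarray(y_test, dtype=np.float64)
    if y.size == 0:
        raise ValueError("baseline_mae requires at least one label")
    return float(np.mean(np.abs(y - y.mean())))


def error_reduction(mae_model: float, mae_baseline: float) -> int:
    """Percent error reduction vs baseline, rounded to the nearest integer."""
    if mae_baseline <= 0:
        raise ValueError("baseline MAE must be positive")
    return int(round(100.0 * (1.0 - mae_model / mae_baseline)))


def patient_level_scores(
    image_scores: Sequence[float],
    patient_ids: Sequence,
    image_labels: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Aggregate image scores to one row per patient (max score, any-positive label)."""
    df = pd.DataFrame({"patient_id": list(patient_ids), "score": np.asarray(image_scores, dtype=float)})
    if image_labels is not None:
        df["label"] = np.asarray(image_labels, dtype=int)
        agg = df.groupby("patient_id").agg(score=("score", "max"), label=("label", "max"))
    else:
        agg = df.groupby("patient_id").agg(score=("score", "max"))
    return agg.reset_index()


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, midrank ties)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def point_biserial(binary: Sequence[int], continuous: Sequence[float]) -> float:
    """Pearson correlation of a 0/1 variable with a continuous variable."""
    b = np.asarray(binary, dtype=float)
    x = np.asarray(continuous, dtype=float)
    if np.var(b) == 0 or np.var(x) == 0:
        raise ValueError("point-biserial correlation undefined for zero-variance input")
    return float(stats.pointbiserialr(b, x).statistic)


def _patient_groups(data: pd.DataFrame, patient_column: str) -> list[np.ndarray]:
    """Row positions per patient, in first-appearance order."""
    codes, _ = pd.factorize(data[patient_column])
    order = np.argsort(codes, kind="stable")
    boundaries = np.flatnonzero(np.diff(codes[order])) + 1
    return np.split(order, boundaries)


def bootstrap_ci(
    metric: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    iterations: int = 5000,
    seed: int = 0,
    patient_column: str = "patient_id",
    max_redraw_factor: int = 10,
) -> tuple[float, float, float, int]:
    """Percentile 95% CI of ``metric`` over patient-level bootstrap resamples.

    ``metric`` receives a DataFrame (rows of resampled patients, each
    patient's images kept together) and returns a scalar. Resamples on which
    the metric is undefined (raises ValueError) are redrawn, up to
    ``max_redraw_factor`` x ``iterations`` attempts; the redraw count is
    returned. The point estimate comes from the full sample.
    """
    point = float(metric(data))
    groups = _patient_groups(data, patient_column)
    rng = np.random.default_rng(seed)
    values: list[float] = []
    redraws = 0
    attempts = 0
    max_attempts = max_redraw_factor * iterations
    while len(values) < iterations:
        if attempts >= max_attempts:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        chosen = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[i] for i in chosen])
        sample = data.take(idx)
        try:
            values.append(float(metric(sample)))
        except ValueError:
            redraws += 1
    lo, hi = np.percentile(values, [2.5, 97.5])
    return point, float(lo), float(hi), redraws


def kde_summary(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    grid_size: int = 64,
    padding: float = 0.15,
) -> dict:
    """2-D Gaussian KDE (Scott bandwidth) of (prediction, ground truth).

    Returns the grid axes (prediction on x, ground truth on y), the density
    on the regular grid (integrating to ~1 over the grid), and the
    annotation values shown on the summary plots (MAE, Pearson r, n).
    """
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) < 10:
        raise ValueError("kde_summary requires at least 10 points")
    if np.var(y_true) == 0 or np.var(y_pred) == 0:
        raise ValueError("kde_summary undefined for zero-variance input")
    kde = stats.gaussian_kde(np.vstack([y_pred, y_true]))  # Scott's rule
    pad = padding * max(np.ptp(y_true), np.ptp(y_pred)) + 3.0 * np.sqrt(kde.covariance.max())
    lo = min(y_pred.min(), y_true.min()) - pad
    hi = max(y_pred.max(), y_true.max()) + pad
    x = np.linspace(lo, hi, grid_size)
    y = np.linspace(lo, hi, grid_size)
    xx, yy = np.meshgrid(x, y)
    density = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    mae, _, r = regression_metrics(y_true, y_pred)
    return {
        "x": x,
        "y": y,
        "density": density,
        "mae": mae,
        "pearson_r": r,
        "n": int(len(y_true)),
        "bandwidth_factor": float(kde.factor),
    }


@dataclass
class MetricCI:
    point: float
    ci_low: float
    ci_high: float


@dataclass
class EvalReport:
    """Point estimates with bootstrap 95% CIs for one experiment cell."""

    task: str
    crop_label: str
    n_images: int
    n_patients: int
    bootstrap_iterations: int = 5000
    bootstrap_seed: int = 0
    mae: Optional[MetricCI] = None
    r2: Optional[MetricCI] = None
    pearson_r: Optional[MetricCI] = None
    auc: Optional[MetricCI] = None
    baseline_mae: Optional[float] = None
    error_reduction_pct: Optional[int] = None
    bootstrap_redraws: int = 0

    def metrics_long(self) -> list[dict]:
        rows = []
        for name in ("mae", "r2", "pearson_r", "auc"):
            ci: Optional[MetricCI] = getattr(self, name)
            if ci is not None:
                rows.append(dict(metric=name, point=ci.point, ci_low=ci.ci_low, ci_high=ci.ci_high))
        return rows

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _regression_stats(t: np.ndarray, p: np.ndarray) -> tuple[float, float, float]:
    mae = float(np.mean(np.abs(t - p)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("zero-variance resample")
    r2 = 1.0 - float(np.sum((t - p) ** 2)) / ss_tot
    sp = p.std()
    if sp == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(t, p)[0, 1])
    return mae, r2, r


def evaluate_regression(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    patient_ids: Sequence,
    crop_label: str = "none",
    iterations: int = 5000,
    seed: int = 0,
) -> EvalReport:
    """Full regression report: per-image metrics, one shared set of
    patient-level bootstrap resamples for all three CIs."""
    data = pd.DataFrame(
        {"patient_id": list(patient_ids), "y_true": np.asarray(y_true, float), "y_pred": np.asarray(y_pred, float)}
    )
    yt = data["y_true"].to_numpy()
    yp = data["y_pred"].to_numpy()
    point_mae, point_r2, point_r = regression_metrics(yt, yp)
    groups = _patient_groups(data, "patient_id")
    rng = np.random.default_rng(seed)
    samples = np.empty((iterations, 3))
    redraws = 0
    filled = 0
    attempts = 0
    while filled < iterations:
        if attempts > 10 * iterations:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        chosen = rng.integers(0, len(groups), size=len(groups))
        idx = np.concatenate([groups[i] for i in chosen])
        try:
            samples[filled] = _regression_stats(yt[idx], yp[idx])
        except ValueError:
            redraws += 1
            continue
        filled += 1
    lo, hi = np.percentile(samples, [2.5, 97.5], axis=0)
    base = baseline_mae(yt)
    return EvalReport(
        task="vcdr",
        crop_label=crop_label,
        n_images=len(data),
        n_patients=int(data["patient_id"].nunique()),
        bootstrap_iterations=iterations,
        bootstrap_seed=seed,
        mae=MetricCI(point_mae, float(lo[0]), float(hi[0])),
        r2=MetricCI(point_r2, float(lo[1]), float(hi[1])),
        pearson_r=MetricCI(point_r, float(lo[2]), float(hi[2])),
        baseline_mae=base,
        error_reduction_pct=error_reduction(point_mae, base),
        bootstrap_redraws=redraws,
    )


def evaluate_classification(
    labels: Sequence[int],
    scores: Sequence[float],
    patient_ids: Sequence,
    crop_label: str = "none",
    iterations: int = 5000,
    seed: int = 0,
) -> EvalReport:
    """Patient-level (max-aggregated) AUC report with bootstrap CI.

    Aggregation to one (label, score) pair per patient happens before
    resampling, so the bootstrap resamples patients directly.
    """
    data = pd.DataFrame(
        {
            "patient_id": list(patient_ids),
            "label": np.asarray(labels, int),
            "score": np.asarray(scores, float),
        }
    )
    agg = patient_level_scores(data["score"], data["patient_id"], data["label"])
    lab = agg["label"].to_numpy()
    sco = agg["score"].to_numpy()
    point = auc(lab, sco)
    rng = np.random.default_rng(seed)
    values = np.empty(iterations)
    redraws = 0
    filled = 0
    attempts = 0
    npat = len(agg)
    while filled < iterations:
        if attempts > 10 * iterations:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, npat, size=npat)
        l, s = lab[idx], sco[idx]
        if l.min() == l.max():
            redraws += 1
            continue
        values[filled] = roc_auc_score(l, s)
        filled += 1
    lo, hi = np.percentile(values, [2.5, 97.5])
    return EvalReport(
        task="glaucoma",
        crop_label=crop_label,
        n_images=len(data),
        n_patients=int(data["patient_id"].nunique()),
        bootstrap_iterations=iterations,
        bootstrap_seed=seed,
        auc=MetricCI(point, float(lo), float(hi)),
        bootstrap_redraws=redraws,
    )
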