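"""Regression metrics, the four-fold CV protocol, ablation suite and
correlation report.

The evaluation protocol holds out 20 % of the cohort as a common test
set, partitions the remainder into four folds, and trains one model per
fold (that fold as validation, the other three as training).  Per-fold
R^2 / MAE / RMSE are computed on the common test set and summarized as
mean +/- sd across folds.  The ablation suite repeats the protocol for
the three information modes (global-only CLS, local-only feature tokens,
and the fused skip-connected head) on shared splits.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
from scipy import stats as sps

from .model import ModelConfig, predict
from .schema import (
    Cohort,
    PreprocessReport,
    SplitPlan,
    apply_standardizer,
    fit_standardizer,
    make_split,
)
from .training import TrainConfig, TrainResult, train

__all__ = [
    "MetricSet",
    "CVResult",
    "r2",
    "mae",
    "rmse",
    "metric_set",
    "crossvalidate",
    "ablation_suite",
    "mean_predictor_baseline",
    "correlation_report",
    "format_correlation_report",
    "calibration_export",
]


def _check(y, yhat, min_n=1):
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    return y, yhat


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (may be negative)."""
    y, yhat = _check(y, yhat, min_n=2)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant observations")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def mae(y, yhat) -> float:
    """Mean absolute error, in days."""
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def rmse(y, yhat) -> float:
    """Root mean squared error, in days (square root applied to the MSE)."""
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class MetricSet:
    r2: float
    mae: float
    rmse: float
    n: int


def metric_set(y, yhat) -> MetricSet:
    return MetricSet(r2=r2(y, yhat), mae=mae(y, yhat), rmse=rmse(y, yhat), n=len(y))


@dataclass
class CVResult:
    per_fold: dict[int, MetricSet]
    split: SplitPlan
    train_results: dict[int, TrainResult] = field(default_factory=dict)
    standardizers: dict[int, PreprocessReport] = field(default_factory=dict)
    test_predictions: dict[int, np.ndarray] = field(default_factory=dict)

    def mean_sd(self) -> dict[str, tuple[float, float]]:
        """Across-fold mean and sample sd per metric."""
        out = {}
        for name in ("r2", "mae", "rmse"):
            vals = np.array([getattr(m, name) for m in self.per_fold.values()])
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[name] = (float(np.mean(vals)), sd)
        return out


def _prepare_fold(cohort, split, fold, pooled_standardize):
    tr_idx, va_idx = split.train_val(fold)
    fit_rows = cohort if pooled_standardize else cohort.subset(tr_idx)
    std = fit_standardizer(fit_rows)
    z = apply_standardizer(cohort, std)
    X = z.features()
    y = cohort.target()
    return std, (X[tr_idx], y[tr_idx]), (X[va_idx], y[va_idx]), (
        X[split.test_indices],
        y[split.test_indices],
    )


def crossvalidate(
    cohort: Cohort,
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    split_seed: int = 0,
    test_fraction: float = 0.2,
    k: int = 4,
    pooled_standardize: bool = False,
    max_folds: int | None = None,
) -> CVResult:
    """Hold out a common test set, train one model per fold, score on test.

    The standardizer is fitted on each fold's training rows only;
    ``pooled_standardize`` fits it on the whole cohort instead, mimicking the
    original single-pass standardization.  Per-fold model/shuffle seeds
    are derived from the configured seeds plus the fold index.
    """
    split = make_split(cohort.n, test_fraction=test_fraction, k=k, seed=split_seed)
    folds = sorted(split.fold_assignments)[: max_folds or k]
    result = CVResult(per_fold={}, split=split)
    for fold in folds:
        std, (Xtr, ytr), (Xva, yva), (Xte, yte) = _prepare_fold(
            cohort, split, fold, pooled_standardize
        )
        mcfg = dc_replace(mconfig, seed=mconfig.seed * 1000 + fold)
        tcfg = dc_replace(tconfig, seed=tconfig.seed * 1000 + fold)
        tr = train(Xtr, ytr, Xva, yva, mcfg, tcfg)
        yhat = predict(Xte, tr.params)
        result.per_fold[fold] = metric_set(yte, yhat)
        result.train_results[fold] = tr
        result.standardizers[fold] = std
        result.test_predictions[fold] = yhat
    return result


MODES = ("global_only", "local_only", "both")


def ablation_suite(
    cohort: Cohort,
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    seeds: list[int],
    max_folds: int | None = None,
    pooled_standardize: bool = False,
) -> dict[str, dict]:
    """Run the CV protocol for each information mode on shared splits.

    Returns mode -> {"mean_sd": {metric: (mean, sd)}, "per_seed":
    [CVResult, ...]}, pooling per-fold test metrics across seeds.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    report: dict[str, dict] = {}
    for mode in MODES:
        per_seed = []
        pooled = {"r2": [], "mae": [], "rmse": []}
        for seed in seeds:
            cv = crossvalidate(
                cohort,
                dc_replace(mconfig, mode=mode, seed=seed),
                dc_replace(tconfig, seed=seed),
                split_seed=seed,
                max_folds=max_folds,
                pooled_standardize=pooled_standardize,
            )
            per_seed.append(cv)
            for m in cv.per_fold.values():
                for name in pooled:
                    pooled[name].append(getattr(m, name))
        report[mode] = {
            "mean_sd": {
                name: (
                    float(np.mean(vals)),
                    float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                )
                for name, vals in pooled.items()
            },
            "per_seed": per_seed,
        }
    return report


def mean_predictor_baseline(cohort: Cohort, split: SplitPlan) -> MetricSet:
    """Trivial baseline: predict the training-pool mean for every test row."""
    y = cohort.target()
    ybar = float(np.mean(y[split.train_pool()]))
    yte = y[split.test_indices]
    return metric_set(yte, np.full(len(yte), ybar))


def correlation_report(cohort: Cohort) -> list[dict]:
    """Per-feature correlation with the target plus a two-sided p-value.

    Pearson r throughout; on a 0/1-coded binary column this is the
    point-biserial correlation.  p-values come from the exact t-transform
    with n-2 degrees of freedom.
    """
    if cohort.n < 3:
        raise ValueError("need at least 3 rows for a correlation report")
    y = cohort.target()
    rows = []
    for name in cohort.schema.feature_names:
        x = cohort.column(name)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"correlation undefined for constant column {name}")
        r, p = sps.pearsonr(x, y)
        rows.append({"feature": name, "coefficient": float(r), "p_value": float(p)})
    return rows


def format_correlation_report(rows: list[dict]) -> str:
    """Human-readable table; p-values below 0.01 print as "< 0.01"."""
    lines = [f"{'feature':10s} {'r':>7s}  p-value"]
    for row in rows:
        p = row["p_value"]
        ptxt = "< 0.01" if p < 0.01 else f"{p:.2f}"
        lines.append(f"{row['feature']:10s} {row['coefficient']:7.2f}  {ptxt}")
    return "\n".join(lines)


def calibration_export(y, yhat, path) -> None:
    """Write (observed, predicted, residual-from-identity) pairs as CSV."""
    y, yhat = _check(y, yhat)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["observed", "predicted", "residual"])
        for yi, pi in zip(y, yhat):
            w.writerow([repr(float(yi)), repr(float(pi)), repr(float(pi - yi))])
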