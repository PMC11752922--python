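"""Shapley-value attribution with an exact enumeration oracle.

Per-feature contributions to a single prediction, in days.  The value of
a feature coalition S is the marginal-expectation convention: the mean
model output over a background sample with the features in S taken from
the explained row and the rest from the background rows.  Two
estimators:

* :func:`shapley_exact` — enumerates all 2^m coalitions and applies the
  Shapley combinatorial weights; efficiency (base value + sum of
  contributions = prediction) holds to float precision.  Practical up to
  the 16-feature model as a slow oracle.
* :func:`shapley_sampled` — averages marginal contributions over random
  feature permutations; each permutation telescopes exactly, so
  efficiency again holds to float precision while per-feature values
  carry Monte-Carlo error.

The base value is the mean model prediction over the background set,
which anchors force plots.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "Attribution",
    "ImportanceSummary",
    "shapley_exact",
    "shapley_sampled",
    "importance_summary",
    "force_export",
]


@dataclass
class Attribution:
    """Additive explanation of one prediction."""

    feature_names: list[str]
    phi: dict[str, float]
    base_value: float
    prediction: float
    n_permutations: int | None = None
    seed: int | None = None

    def efficiency_gap(self) -> float:
        return abs(self.base_value + sum(self.phi.values()) - self.prediction)


@dataclass
class ImportanceSummary:
    mean_abs: dict[str, float]
    ranking: list[str]


def _as_matrix(data) -> np.ndarray:
    if hasattr(data, "features"):  # Cohort
        return data.features()
    return np.atleast_2d(np.asarray(data, dtype=float))


def _coalition_value(predict_fn, x, background, mask) -> float:
    hybrid = background.copy()
    hybrid[:, mask] = x[mask]
    return float(np.mean(predict_fn(hybrid)))


def shapley_exact(predict_fn, x, background, feature_names=None) -> Attribution:
    """Exact Shapley values by coalition enumeration (O(2^m) model calls)."""
    x = np.asarray(x, dtype=float).ravel()
    bg = _as_matrix(background)
    if bg.size == 0:
        raise ValueError("background set is empty")
    m = x.size
    if m > 16:
        raise ValueError(f"exact enumeration limited to 16 features, got {m}")
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(m)
    ]
    values = np.empty(2**m)
    for s in range(2**m):
        mask = np.array([(s >> i) & 1 for i in range(m)], dtype=bool)
        values[s] = _coalition_value(predict_fn, x, bg, mask)
    fact = [factorial(i) for i in range(m + 1)]
    phi = np.zeros(m)
    for s in range(2**m):
        size = bin(s).count("1")
        w = fact[size] * fact[m - size - 1] / fact[m]
        for i in range(m):
            if not (s >> i) & 1:
                phi[i] += w * (values[s | (1 << i)] - values[s])
    base = float(values[0])
    pred = float(values[2**m - 1])
    return Attribution(
        feature_names=names,
        phi={n: float(p) for n, p in zip(names, phi)},
        base_value=base,
        prediction=pred,
    )


def shapley_sampled(
    predict_fn, x, background, n_permutations: int = 200, seed: int = 0,
    feature_names=None,
) -> Attribution:
    """Permutation-sampling Shapley estimator.

    For each sampled permutation, features are switched from background
    to the explained row one at a time; the successive coalition-value
    differences are that permutation's contributions.  The per-permutation
    telescoping sum equals prediction - base value exactly, so the
    averaged attribution satisfies efficiency to float precision.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    x = np.asarray(x, dtype=float).ravel()
    bg = _as_matrix(background)
    if bg.size == 0:
        raise ValueError("background set is empty")
    m = x.size
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(m)
    ]
    rng = np.random.default_rng(seed)
    base = float(np.mean(predict_fn(bg)))
    pred = _coalition_value(predict_fn, x, bg, np.ones(m, dtype=bool))
    phi = np.zeros(m)
    for _ in range(n_permutations):
        order = rng.permutation(m)
        # one stacked model call per permutation: m partial coalitions
        B = bg.shape[0]
        batches = np.empty((m, B, m))
        hybrid = bg.copy()
        for step, j in enumerate(order):
            hybrid[:, j] = x[j]
            batches[step] = hybrid
        preds = predict_fn(batches.reshape(m * B, m)).reshape(m, B).mean(axis=1)
        prev = base
        for step, j in enumerate(order):
            phi[j] += preds[step] - prev
            prev = preds[step]
    phi /= n_permutations
    return Attribution(
        feature_names=names,
        phi={n: float(p) for n, p in zip(names, phi)},
        base_value=base,
        prediction=pred,
        n_permutations=n_permutations,
        seed=seed,
    )


def importance_summary(attributions: list[Attribution]) -> ImportanceSummary:
    """Mean |phi| per feature across patients, ranked descending."""
    if not attributions:
        raise ValueError("no attributions given")
    names = attributions[0].feature_names
    for a in attributions:
        if a.feature_names != names:
            raise ValueError("attributions have mismatched feature sets")
    mean_abs = {
        n: float(np.mean([abs(a.phi[n]) for a in attributions])) for n in names
    }
    ranking = sorted(names, key=lambda n: -mean_abs[n])
    return ImportanceSummary(mean_abs=mean_abs, ranking=ranking)


def force_export(attribution: Attribution, path, raw_values=None) -> None:
    """CSV with base value, per-feature (name, raw value, phi), prediction.

    ``raw_values`` optionally maps feature name -> the patient's raw
    (unstandardized) value for force-plot labeling.
    """
    raw_values = raw_values or {}
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record", "raw_value", "phi_days"])
        w.writerow(["base_value", "", repr(float(attribution.base_value))])
        for name in attribution.feature_names:
            w.writerow(
                [name, raw_values.get(name, ""), repr(float(attribution.phi[name]))]
            )
        w.writerow(["prediction", "", repr(float(attribution.prediction))])
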