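"""Feature schema, cohort container, CSV I/O and preprocessing.

The cohort is a rectangular table of sepsis patients: 16 input features
(10 clinical, 6 SOFA-related) plus the regression target, ICU length of
stay in days.  Preprocessing follows the study protocol: IQR-rule outlier
removal on the target, z-score standardization of numeric features, and a
held-out-test + k-fold split of the remainder.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FeatureEntry",
    "FeatureSchema",
    "Cohort",
    "PreprocessReport",
    "SplitPlan",
    "ValidationError",
    "default_schema",
    "read_cohort",
    "write_cohort",
    "iqr_bounds",
    "filter_outliers",
    "fit_standardizer",
    "apply_standardizer",
    "make_split",
]

KINDS = ("numeric", "integer", "binary")
ROLES = ("clinical", "sofa", "target")

#: Accepted text labels for binary columns (case-insensitive) -> {0, 1}.
BINARY_LABELS = {
    "yes": 1, "no": 0,
    "male": 1, "female": 0,
    "1": 1, "0": 0,
    "true": 1, "false": 0,
}


class ValidationError(ValueError):
    """A cohort table violated the schema contract."""


@dataclass(frozen=True)
class FeatureEntry:
    """One column of the cohort: name, value kind, unit and role."""

    name: str
    kind: str
    unit: str
    role: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered column schema with exactly one target entry.

    Attributes
    ----------
    entries : tuple of FeatureEntry
        Columns in canonical order; the target may sit anywhere but by
        convention comes last.
    """

    entries: tuple[FeatureEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in schema")
        n_target = sum(e.role == "target" for e in self.entries)
        if n_target != 1:
            raise ValueError(f"schema needs exactly one target entry, got {n_target}")

    @property
    def col(self) -> int:
        """Number of non-target (input) columns."""
        return len(self.entries) - 1

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def target(self) -> FeatureEntry:
        return next(e for e in self.entries if e.role == "target")

    @property
    def feature_entries(self) -> list[FeatureEntry]:
        return [e for e in self.entries if e.role != "target"]

    @property
    def feature_names(self) -> list[str]:
        return [e.name for e in self.feature_entries]

    @property
    def binary_names(self) -> list[str]:
        return [e.name for e in self.entries if e.kind == "binary"]

    @property
    def numeric_feature_names(self) -> list[str]:
        """Non-binary, non-target column names (standardization candidates)."""
        return [
            e.name
            for e in self.feature_entries
            if e.kind in ("numeric", "integer")
        ]

    def entry(self, name: str) -> FeatureEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def default_schema() -> FeatureSchema:
    """The 17-column sepsis schema: 10 clinical + 6 SOFA features + ICU LOS.

    Binary features are sex (male=1), AF, VASO and MV; GCS is an integer
    score on 3..15.  The BMI unit string reproduces the source table
    verbatim (kg/cm^2, presumably kg/m^2).
    """
    c, s = "clinical", "sofa"
    entries = (
        FeatureEntry("age", "numeric", "years", c),
        FeatureEntry("sex", "binary", "male=1", c),
        FeatureEntry("BMI", "numeric", "kg/cm^2", c),  # sic; presumably kg/m^2
        FeatureEntry("lactate", "numeric", "mmol/L", c),
        FeatureEntry("AF", "binary", "yes=1", c),
        FeatureEntry("SBP", "numeric", "mmHg", c),
        FeatureEntry("DBP", "numeric", "mmHg", c),
        FeatureEntry("MBP", "numeric", "mmHg", c),
        FeatureEntry("PF", "numeric", "-", c),
        FeatureEntry("GCS", "integer", "-", c),
        FeatureEntry("VASO", "binary", "yes=1", s),
        FeatureEntry("MV", "binary", "yes=1", s),
        FeatureEntry("UR", "numeric", "cm^3", s),
        FeatureEntry("Plt", "numeric", "x10^3/uL", s),
        FeatureEntry("Bil", "numeric", "mg/dL", s),
        FeatureEntry("Cr", "numeric", "mg/dL", s),
        FeatureEntry("ICU_LOS", "numeric", "days", "target"),
    )
    return FeatureSchema(entries)


@dataclass
class Cohort:
    """A validated patient table conforming to a :class:`FeatureSchema`."""

    schema: FeatureSchema
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame, self.schema)

    @property
    def n(self) -> int:
        return len(self.frame)

    def features(self) -> np.ndarray:
        """(n, col) float array of input features in schema order."""
        return self.frame[self.schema.feature_names].to_numpy(dtype=float)

    def target(self) -> np.ndarray:
        """(n,) float array of ICU LOS in days."""
        return self.frame[self.schema.target.name].to_numpy(dtype=float)

    def subset(self, indices: Sequence[int]) -> "Cohort":
        sub = self.frame.iloc[np.asarray(indices)].reset_index(drop=True)
        return Cohort(self.schema, sub)

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)


def _validate_frame(frame: pd.DataFrame, schema: FeatureSchema) -> pd.DataFrame:
    missing = [n for n in schema.names if n not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    out = {}
    for e in schema.entries:
        col = frame[e.name]
        if col.isna().any():
            row = int(col.index[col.isna()][0])
            raise ValidationError(f"missing cell at row {row}, column {e.name}")
        if e.kind == "binary":
            vals = _coerce_binary(col, e.name)
        else:
            try:
                vals = pd.to_numeric(col, errors="raise").astype(float)
            except (ValueError, TypeError) as err:
                raise ValidationError(f"unparseable value in column {e.name}: {err}")
            if e.kind == "integer" and not np.allclose(vals, np.round(vals)):
                row = int(np.nonzero(~np.isclose(vals, np.round(vals)))[0][0])
                raise ValidationError(
                    f"non-integer value at row {row}, column {e.name}"
                )
        if e.role == "target" and (np.asarray(vals) <= 0).any():
            row = int(np.nonzero(np.asarray(vals) <= 0)[0][0])
            raise ValidationError(
                f"non-positive target at row {row}, column {e.name}"
            )
        out[e.name] = np.asarray(vals, dtype=float)
    return pd.DataFrame(out, columns=schema.names)


def _coerce_binary(col: pd.Series, name: str) -> np.ndarray:
    out = np.empty(len(col), dtype=float)
    for i, v in enumerate(col.to_numpy()):
        if isinstance(v, str):
            key = v.strip().lower()
            if key not in BINARY_LABELS:
                raise ValidationError(
                    f"out-of-domain binary value {v!r} at row {i}, column {name}"
                )
            out[i] = BINARY_LABELS[key]
        else:
            fv = float(v)
            if fv not in (0.0, 1.0):
                raise ValidationError(
                    f"out-of-domain binary value {v!r} at row {i}, column {name}"
                )
            out[i] = fv
    return out


def read_cohort(path, schema: FeatureSchema | None = None) -> Cohort:
    """Read and validate a cohort CSV (header row; any column order)."""
    schema = schema or default_schema()
    frame = pd.read_csv(path)
    return Cohort(schema, frame)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as RFC-4180 CSV with full float precision."""
    cohort.frame.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing


@dataclass
class PreprocessReport:
    """Fitted preprocessing state: IQR bounds and/or standardizer.

    ``standardizer`` maps column name -> (mean, sample sd).  Bounds are in
    days and refer to the target column the filter was fitted on.
    """

    lower_bound: float | None = None
    upper_bound: float | None = None
    n_excluded: int | None = None
    standardizer: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        doc = {
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "n_excluded": self.n_excluded,
            "standardizer": {
                k: {"mean": float(m), "sd": float(s)}
                for k, (m, s) in self.standardizer.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PreprocessReport":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            lower_bound=doc.get("lower_bound"),
            upper_bound=doc.get("upper_bound"),
            n_excluded=doc.get("n_excluded"),
            standardizer={
                k: (v["mean"], v["sd"])
                for k, v in (doc.get("standardizer") or {}).items()
            },
        )


def iqr_bounds(
    values: Iterable[float], multiplier: float = 1.5
) -> tuple[float, float]:
    """Tukey-fence bounds (Q1 - m*IQR, Q3 + m*IQR).

    Quartiles use linear interpolation between order statistics (the
    "type 7" convention of mainstream numeric stacks).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 values for IQR bounds, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    iqr = q3 - q1
    return float(q1 - multiplier * iqr), float(q3 + multiplier * iqr)


def filter_outliers(
    cohort: Cohort, multiplier: float = 1.5
) -> tuple[Cohort, PreprocessReport]:
    """Drop rows whose target lies strictly outside the IQR fences."""
    y = cohort.target()
    lo, hi = iqr_bounds(y, multiplier)
    keep = (y >= lo) & (y <= hi)
    report = PreprocessReport(
        lower_bound=lo, upper_bound=hi, n_excluded=int((~keep).sum())
    )
    kept = Cohort(cohort.schema, cohort.frame.loc[keep].reset_index(drop=True))
    return kept, report


def fit_standardizer(
    cohort: Cohort, columns: Sequence[str] | None = None
) -> PreprocessReport:
    """Fit per-column (mean, sample sd) for z-scoring.

    Binary columns and the target are never standardized; by default all
    numeric/integer input columns are fitted.
    """
    if columns is None:
        columns = cohort.schema.numeric_feature_names
    standardizer: dict[str, tuple[float, float]] = {}
    for name in columns:
        e = cohort.schema.entry(name)
        if e.role == "target" or e.kind == "binary":
            raise ValueError(f"column {name} is not standardizable ({e.kind}/{e.role})")
        vals = cohort.column(name)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if sd <= 0:
            raise ValueError(f"zero-variance column {name}: cannot standardize")
        standardizer[name] = (mean, sd)
    return PreprocessReport(standardizer=standardizer)


def apply_standardizer(cohort: Cohort, report: PreprocessReport) -> Cohort:
    """Apply Z = (X - mean)/sd per stored column; other columns untouched."""
    frame = cohort.frame.copy()
    for name, (mean, sd) in report.standardizer.items():
        if name not in frame.columns:
            raise ValueError(f"standardized column {name} absent from cohort")
        frame[name] = (frame[name] - mean) / sd
    # bypass validation: standardized values legitimately leave raw domains
    out = object.__new__(Cohort)
    out.schema = cohort.schema
    out.frame = frame
    return out


# ---------------------------------------------------------------------------
# Splitting


@dataclass
class SplitPlan:
    """Held-out test indices plus a k-fold partition of the training pool."""

    test_indices: np.ndarray
    fold_assignments: dict[int, np.ndarray]
    seed: int

    @property
    def k(self) -> int:
        return len(self.fold_assignments)

    def train_pool(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.fold_assignments.values())))

    def train_val(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Training indices (all other folds) and validation indices."""
        val = self.fold_assignments[fold]
        train = np.concatenate(
            [v for f, v in self.fold_assignments.items() if f != fold]
        )
        return train, val

    def to_yaml(self, path) -> None:
        doc = {
            "seed": int(self.seed),
            "test_indices": [int(i) for i in self.test_indices],
            "folds": {
                int(f): [int(i) for i in v]
                for f, v in self.fold_assignments.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SplitPlan":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            test_indices=np.array(doc["test_indices"], dtype=int),
            fold_assignments={
                int(f): np.array(v, dtype=int) for f, v in doc["folds"].items()
            },
            seed=int(doc["seed"]),
        )


def make_split(
    n_or_cohort, test_fraction: float = 0.2, k: int = 4, seed: int = 0
) -> SplitPlan:
    """Seed-deterministic uniform split: round(n*test_fraction) test rows,
    the rest partitioned into k near-equal folds (sizes differ by <= 1)."""
    n = n_or_cohort.n if isinstance(n_or_cohort, Cohort) else int(n_or_cohort)
    if n < k + 1:
        raise ValueError(f"cannot split n={n} into a test set and {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test = np.sort(perm[:n_test])
    pool = perm[n_test:]
    folds = {
        i + 1: np.sort(chunk)
        for i, chunk in enumerate(np.array_split(pool, k))
    }
    if any(len(v) == 0 for v in folds.values()):
        raise ValueError("degenerate split: empty fold")
    return SplitPlan(test_indices=test, fold_assignments=folds, seed=seed)
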