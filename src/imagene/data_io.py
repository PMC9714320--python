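"""Feature-table I/O, sample matching, omics screening, splitting and scaling.

A :class:`FeatureTable` is the package's in-memory container for one of the
two inputs of a radiogenomic experiment: a samples × features numeric matrix
with a declared role (``imaging`` or ``omics``).  The two tables are matched
on sample IDs, optionally screened (omics), split into train/test once, and
normalized with one of three scalers.  By default the scaler is fitted
independently on the training and test partitions (the same technique, fitted
twice) so that no test statistics leak into training; ``fit="train_only"``
gives the conventional fit-on-train/apply-to-test behaviour instead.

All standard deviations use the population convention (``ddof=0``) so that
the evaluation module's identity R² = 1 − v² holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Role = Literal["imaging", "omics"]
ScalerMethod = Literal["stand_scaler", "min_max", "max_abs"]

SCALER_METHODS = ("stand_scaler", "min_max", "max_abs")

#: Canonical name of the sample-ID column in the CSV dialect.
SAMPLE_COLUMN = "Sample"


class ValidationError(ValueError):
    """Input table violates a structural invariant (duplicates, NaNs, ...)."""


class ConfigError(ValueError):
    """A configuration value is outside its legal domain."""


@dataclass
class FeatureTable:
    """Samples × features numeric matrix with IDs, names and a role.

    Invariants (checked in ``__post_init__``): unique sample IDs, unique
    feature names, matching dimensions, all entries finite.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    role: Role

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n == 0 or p == 0:
            raise ValidationError("empty feature table")
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample IDs for {n} rows"
            )
        if len(self.feature_names) != p:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        dup = _first_duplicate(self.feature_names)
        if dup is not None:
            raise ValidationError(f"duplicate feature name: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_names[c]!r}"
            )
        if self.role not in ("imaging", "omics"):
            raise ValidationError(f"unknown role {self.role!r}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_names
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, role: Role) -> "FeatureTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            role=role,
        )

    def select_features(self, names: list[str]) -> "FeatureTable":
        """Restrict to the named features, in the given order."""
        idx = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in idx]
        if missing:
            raise ValidationError(f"unknown feature(s): {missing}")
        cols = [idx[f] for f in names]
        return FeatureTable(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols],
            role=self.role,
        )

    def select_samples(self, ids: list[str]) -> "FeatureTable":
        """Restrict to the named samples, in the given order."""
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown sample(s): {missing}")
        rows = [idx[s] for s in ids]
        return FeatureTable(
            sample_ids=list(ids),
            feature_names=list(self.feature_names),
            values=self.values[rows],
            role=self.role,
        )


def _first_duplicate(items: list[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_feature_table(path: str | Path, role: Role) -> FeatureTable:
    """Load a CSV feature table (samples in rows, features in columns).

    The first column holds sample IDs; the header row holds feature names.
    Every remaining cell must parse as a finite number — missing or
    non-numeric cells are rejected with coordinates rather than imputed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty table")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j].strip()
            try:
                v = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
            if not np.isfinite(v) or cell == "":
                raise ValidationError(
                    f"{path}: missing/non-finite value at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                )
            values[i, j] = v
    return FeatureTable(
        sample_ids=[str(s) for s in df.index],
        feature_names=[str(c) for c in df.columns],
        values=values,
        role=role,
    )


def save_feature_table(t: FeatureTable, path: str | Path) -> None:
    """Write a table back out in the same CSV dialect it is read in."""
    df = t.to_frame()
    df.index.name = SAMPLE_COLUMN
    df.to_csv(path, float_format="%.10g")


# ---------------------------------------------------------------------------
# Sample matching and omics screening
# ---------------------------------------------------------------------------

def match_samples(
    a: FeatureTable, b: FeatureTable
) -> tuple[FeatureTable, FeatureTable]:
    """Restrict both tables to their common samples, in identical row order.

    Matching is exact (case-sensitive) on the ID strings.  The common IDs
    keep the order in which they appear in ``a``.
    """
    in_b = set(b.sample_ids)
    common = [s for s in a.sample_ids if s in in_b]
    if not common:
        raise ValidationError("zero common samples between the two tables")
    return a.select_samples(common), b.select_samples(common)


def screen_omics(
    t: FeatureTable, min_value: float, min_samples: int
) -> FeatureTable:
    """Keep features whose value is ≥ ``min_value`` in ≥ ``min_samples`` samples.

    The screening rule used for expression tables (e.g. FPKM ≥ 5 in ≥ 30
    patients) before correlation analysis; the sample set is unchanged.
    """
    if t.role != "omics":
        raise ConfigError("screen_omics expects an omics table")
    if min_samples > t.n_samples:
        raise ConfigError(
            f"min_samples={min_samples} exceeds n_samples={t.n_samples}"
        )
    counts = (t.values >= min_value).sum(axis=0)
    keep = [f for f, c in zip(t.feature_names, counts) if c >= min_samples]
    if not keep:
        raise ValidationError("screening removed every omics feature")
    return t.select_features(keep)


# ---------------------------------------------------------------------------
# Train/test split
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    """Uniform random, seeded train/test partition (no stratification)."""

    train_fraction: float = 0.9
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, f in (
            ("train_fraction", self.train_fraction),
            ("test_fraction", self.test_fraction),
        ):
            if not (0.0 < f < 1.0):
                raise ConfigError(f"{name}={f} must lie in (0, 1)")
        if self.train_fraction + self.test_fraction > 1.0 + 1e-12:
            raise ConfigError("train_fraction + test_fraction exceeds 1")


def split_train_test(
    x: FeatureTable, y: FeatureTable, spec: SplitSpec
) -> tuple[tuple[FeatureTable, FeatureTable], tuple[FeatureTable, FeatureTable]]:
    """Apply one seeded sample partition to both tables.

    Test size is ``round(test_fraction * n)``; the remainder of the
    train+test budget goes to training.  Deterministic given the seed.
    """
    if x.sample_ids != y.sample_ids:
        raise ValidationError("tables must be sample-matched before splitting")
    n = x.n_samples
    n_test = int(round(spec.test_fraction * n))
    if spec.train_fraction + spec.test_fraction >= 1.0 - 1e-12:
        n_train = n - n_test
    else:
        n_train = int(round(spec.train_fraction * n))
    if n_test < 1 or n_train < 1:
        raise ConfigError(
            f"split of n={n} gives train={n_train}, test={n_test}; "
            "both must be non-empty"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    test_rows = sorted(perm[:n_test].tolist())
    train_rows = sorted(perm[n_test : n_test + n_train].tolist())
    train_ids = [x.sample_ids[i] for i in train_rows]
    test_ids = [x.sample_ids[i] for i in test_rows]
    return (
        (x.select_samples(train_ids), y.select_samples(train_ids)),
        (x.select_samples(test_ids), y.select_samples(test_ids)),
    )


# ---------------------------------------------------------------------------
# Scalers
# ---------------------------------------------------------------------------

@dataclass
class ScalerParams:
    """Fitted per-feature normalization statistics.

    ``stand_scaler`` stores (mean, population std); ``min_max`` stores
    (min, max); ``max_abs`` stores (0, max |x|).  Constant features (zero
    std / zero range) are mapped to 0 with a warning.
    """

    method: ScalerMethod
    feature_names: list[str]
    center: np.ndarray  # mean | min | 0
    scale: np.ndarray   # std | (max - min) | max-abs; 0 marks constant cols

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "feature_names": list(self.feature_names),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(
            method=d["method"],
            feature_names=list(d["feature_names"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )


def fit_scaler(t: FeatureTable, method: ScalerMethod) -> ScalerParams:
    if method not in SCALER_METHODS:
        raise ConfigError(
            f"unknown scaler {method!r}; choose from {SCALER_METHODS}"
        )
    v = t.values
    if method == "stand_scaler":
        center = v.mean(axis=0)
        scale = v.std(axis=0, ddof=0)
    elif method == "min_max":
        center = v.min(axis=0)
        scale = v.max(axis=0) - center
    else:  # max_abs
        center = np.zeros(t.n_features)
        scale = np.abs(v).max(axis=0)
    if np.any(scale == 0):
        bad = [f for f, s in zip(t.feature_names, scale) if s == 0]
        warnings.warn(
            f"constant feature(s) mapped to 0 under {method}: {bad}",
            stacklevel=2,
        )
    return ScalerParams(
        method=method,
        feature_names=list(t.feature_names),
        center=center,
        scale=scale,
    )


def apply_scaler(t: FeatureTable, p: ScalerParams) -> FeatureTable:
    if list(t.feature_names) != list(p.feature_names):
        raise ValidationError(
            "scaler params were fitted on different feature names"
        )
    safe = np.where(p.scale == 0, 1.0, p.scale)
    out = (t.values - p.center) / safe
    out[:, p.scale == 0] = 0.0  # constant-feature guard
    return FeatureTable(
        sample_ids=list(t.sample_ids),
        feature_names=list(t.feature_names),
        values=out,
        role=t.role,
    )


def invert_scaler(t: FeatureTable, p: ScalerParams) -> FeatureTable:
    """Map a scaled table back to original units (non-constant features)."""
    if list(t.feature_names) != list(p.feature_names):
        raise ValidationError(
            "scaler params were fitted on different feature names"
        )
    return FeatureTable(
        sample_ids=list(t.sample_ids),
        feature_names=list(t.feature_names),
        values=t.values * p.scale + p.center,
        role=t.role,
    )
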