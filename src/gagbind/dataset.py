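"""Feature-table handling: scaling, splitting, subsampling and metrics.

A :class:`FeatureTable` is a thin wrapper over a pandas DataFrame holding
metadata columns, an ordered list of feature columns and (for supervised use)
an MM-GBSA target column in kcal/mol.  Row order is kept
(system, trajectory, frame) lexicographic by construction, so every-kth
subsampling interacts with the time correlation of MD-derived rows the way a
stride through a trajectory would.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.preprocessing import StandardScaler

from gagbind.descriptors import FEATURE_NAMES, METADATA_COLUMNS, TARGET_COLUMN

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Rectangular feature table with metadata, features and optional target."""

    df: pd.DataFrame
    feature_names: tuple[str, ...]
    target_column: str | None = TARGET_COLUMN

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        missing = [c for c in self.feature_names if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature columns absent from table: {missing}")
        if self.target_column is not None and self.target_column not in self.df.columns:
            self.target_column = None

    def __len__(self) -> int:
        return len(self.df)

    @property
    def X(self) -> np.ndarray:
        return self.df[list(self.feature_names)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.target_column is None:
            raise ValueError("table has no target column")
        return self.df[self.target_column].to_numpy(dtype=float)

    def dropna(self) -> "FeatureTable":
        """Drop (and log) rows with any missing feature or target value."""
        cols = list(self.feature_names) + ([self.target_column] if self.target_column else [])
        keep = self.df[cols].notna().all(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d rows with missing values", dropped)
        return FeatureTable(self.df.loc[keep].reset_index(drop=True),
                            self.feature_names, self.target_column)

    def select(self, features: tuple[str, ...]) -> "FeatureTable":
        return FeatureTable(self.df, tuple(features), self.target_column)

    def take(self, index: np.ndarray) -> "FeatureTable":
        return FeatureTable(self.df.iloc[index].reset_index(drop=True),
                            self.feature_names, self.target_column)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_feature_table(
    path,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    target_column: str | None = TARGET_COLUMN,
    column_map: dict[str, str] | None = None,
) -> FeatureTable:
    """Load a CSV feature table, optionally renaming external column names.

    ``column_map`` maps external column names onto the canonical feature IDs
    (and target column) so externally produced descriptor tables can be fed
    into the benchmark unchanged.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    present = tuple(f for f in feature_names if f in df.columns)
    if not present:
        raise ValueError(f"no recognised feature columns in {path}")
    return FeatureTable(df, present, target_column)


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class ScalerParams:
    """Training-set per-feature mean/std (population), with constant columns dropped."""

    feature_names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerParams":
        return cls(tuple(d["feature_names"]), np.asarray(d["mean"]), np.asarray(d["std"]))


def zscore_fit(table: FeatureTable) -> ScalerParams:
    """Fit per-feature standardisation statistics on the training table only."""
    if len(table) < 2:
        raise ValueError("need >= 2 rows to fit a scaler")
    scaler = StandardScaler()
    scaler.fit(table.X)
    std = np.asarray(scaler.scale_, dtype=float)
    mean = np.asarray(scaler.mean_, dtype=float)
    # StandardScaler maps zero-variance columns to scale 1; detect them directly
    keep = np.asarray(scaler.var_, dtype=float) > 0
    if not keep.all():
        dropped = [f for f, k in zip(table.feature_names, keep) if not k]
        logger.warning("dropping constant feature column(s): %s", dropped)
    names = tuple(f for f, k in zip(table.feature_names, keep) if k)
    return ScalerParams(names, mean[keep], std[keep])


def zscore_apply(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """Apply training-set statistics to any table (train, test or validation)."""
    df = table.df.copy()
    for name, mu, sd in zip(params.feature_names, params.mean, params.std):
        df[name] = (df[name].to_numpy(dtype=float) - mu) / sd
    return FeatureTable(df, params.feature_names, table.target_column)


# ---------------------------------------------------------------------------
# Splits and subsampling


def split_random(
    table: FeatureTable, test_fraction: float = 0.2, seed: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Seeded random 80/20-style row split; test gets floor(n * fraction) rows."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError(f"need >= 5 rows to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = math.floor(n * test_fraction)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return table.take(train_idx), table.take(test_idx)


def split_group_holdout(
    table: FeatureTable, group_key: str, held_groups: list
) -> tuple[FeatureTable, FeatureTable]:
    """Hold out whole groups (e.g. one cathepsin subtype) as a validation set."""
    if not held_groups:
        raise ValueError("held_groups must be non-empty")
    groups = table.df[group_key]
    present = set(groups.unique().tolist())
    absent = [g for g in held_groups if g not in present]
    if absent:
        raise ValueError(f"held group(s) absent from table: {absent}")
    held = groups.isin(held_groups).to_numpy()
    if held.all():
        raise ValueError("empty development set: all groups held out")
    return table.take(np.flatnonzero(~held)), table.take(np.flatnonzero(held))


def subsample_every_kth(table: FeatureTable, k: int) -> FeatureTable:
    """Keep rows with index = 0 (mod k), preserving order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return table.take(np.arange(0, len(table), k))


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class Metrics:
    r2: float
    mse: float  # kcal^2/mol^2
    mae: float  # kcal/mol

    def as_dict(self) -> dict:
        return {"r2": self.r2, "mse": self.mse, "mae": self.mae}


def compute_metrics(predicted: np.ndarray, actual: np.ndarray) -> Metrics:
    """R^2 (against the evaluated set's own mean), MSE and MAE."""
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1:
        raise ValueError("predicted and actual must be 1-D arrays of equal length")
    if len(actual) < 2:
        raise ValueError("need >= 2 values to compute metrics")
    if np.var(actual) == 0:
        logger.warning("zero target variance; R^2 undefined (reported as NaN)")
        r2 = float("nan")
    else:
        r2 = float(r2_score(actual, predicted))
    return Metrics(
        r2=r2,
        mse=float(mean_squared_error(actual, predicted)),
        mae=float(mean_absolute_error(actual, predicted)),
    )
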