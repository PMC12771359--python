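"""Benchmark experiments: correlation structure, importance, ablation, sweeps.

This module drives the model-comparison protocol end to end on any feature
table: Pearson correlation matrices with hierarchical clustering of
descriptors, four feature-importance mechanisms (coefficients, built-in tree
importances, permutation importance, leave-one-feature-out retraining), the
eight-family benchmark with and without the LIE energetic descriptors, the
FCNN architecture/dropout/activation sweep, the training-data reduction
curve, and the trajectory-level evaluations (trajectory-mean prediction and
first-frame screening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from gagbind.dataset import (
    FeatureTable,
    Metrics,
    compute_metrics,
    split_random,
    subsample_every_kth,
    zscore_apply,
    zscore_fit,
)
from gagbind.descriptors import LIE_FEATURES
from gagbind.models import (
    LINEAR_FAMILIES,
    ModelConfig,
    ModelFamily,
    RepetitionReport,
    TrainedModel,
    predict,
    run_repetitions,
    train,
)
from gagbind.nn import FCNNRegressor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Correlation structure


@dataclass
class CorrelationMatrix:
    labels: tuple[str, ...]
    r: pd.DataFrame           # symmetric Pearson r, diagonal 1
    linkage: np.ndarray | None = None
    leaf_order: tuple[int, ...] | None = None


def pearson_matrix(table: FeatureTable, include_target: bool = True) -> CorrelationMatrix:
    """Pairwise Pearson correlations of features (optionally plus the target)."""
    if len(table) < 3:
        raise ValueError("need >= 3 rows for a correlation matrix")
    cols = list(table.feature_names)
    data = table.df[cols].astype(float)
    if include_target and table.target_column:
        cols = cols + [table.target_column]
        data = table.df[cols].astype(float)
    constant = [c for c in cols if data[c].std() == 0]
    if constant:
        logger.warning("constant column(s), correlations undefined (NaN): %s", constant)
    r = data.corr(method="pearson")
    return CorrelationMatrix(tuple(cols), r)


def cluster_features(matrix: CorrelationMatrix) -> CorrelationMatrix:
    """Average-linkage agglomerative clustering on distance 1 - |r|.

    Redundancy between descriptors is about correlation magnitude, not sign,
    hence the absolute value in the distance.  Leaf order is made
    deterministic by scipy's index tie-breaking on the condensed matrix.
    """
    r = matrix.r.to_numpy(copy=True)
    np.fill_diagonal(r, 1.0)
    dist = 1.0 - np.abs(np.nan_to_num(r, nan=0.0))
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    order = tuple(int(i) for i in hierarchy.leaves_list(link))
    return CorrelationMatrix(matrix.labels, matrix.r, link, order)


# ---------------------------------------------------------------------------
# Feature importance


@dataclass
class ImportanceReport:
    method: str  # COEFFICIENTS | BUILTIN | PERMUTATION | LOFO_MSE | SHAPLEY
    family: str
    features: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    note: str = ""

    def ranking(self) -> tuple[str, ...]:
        order = np.argsort(-np.abs(self.raw))
        return tuple(self.features[i] for i in order)

    def top_feature(self) -> str:
        return self.ranking()[0]


def _normalize(raw: np.ndarray) -> np.ndarray:
    peak = np.max(np.abs(raw)) if len(raw) else 0.0
    return raw / peak if peak > 0 else np.zeros_like(raw)


def fit_on(config: ModelConfig, table: FeatureTable) -> TrainedModel:
    """Scale a raw table (its own statistics) and fit one model on all rows."""
    scaler = zscore_fit(table)
    return train(config, zscore_apply(table, scaler), scaler=scaler)


def predict_raw(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict on a raw (unscaled) table using the model's stored scaler."""
    if model.scaler is None:
        return predict(model, table.select(model.feature_names))
    scaled = zscore_apply(table, model.scaler)
    return predict(model, scaled)


def coefficient_importance(model: TrainedModel) -> ImportanceReport:
    """Absolute standardized coefficients, normalized to max 1 (linear families)."""
    est = model.estimator
    if isinstance(est, FCNNRegressor) and not est.config.hidden_sizes:
        coefs = np.asarray(est.linear_weights, dtype=float)
    elif model.config.family in LINEAR_FAMILIES and hasattr(est, "coef_"):
        coefs = np.asarray(est.coef_, dtype=float).ravel()
    else:
        raise ValueError(
            f"unsupported method: {model.config.family.name} has no feature coefficients"
        )
    return ImportanceReport(
        "COEFFICIENTS", model.config.family.name, model.feature_names,
        coefs, _normalize(coefs),
    )


def builtin_importance(model: TrainedModel) -> ImportanceReport:
    est = model.estimator
    if not hasattr(est, "feature_importances_"):
        raise ValueError(
            f"unsupported method: {model.config.family.name} has no built-in importances"
        )
    raw = np.asarray(est.feature_importances_, dtype=float)
    return ImportanceReport(
        "BUILTIN", model.config.family.name, model.feature_names, raw, _normalize(raw)
    )


def permutation_importance(
    model: TrainedModel,
    table: FeatureTable,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Mean MSE increase when one (scaled) feature column is shuffled."""
    rng = np.random.default_rng(seed)
    X = table.X.copy()
    y = table.y
    base_mse = float(np.mean((model.estimator.predict(X) - y) ** 2))
    raw = np.zeros(len(table.feature_names))
    for fi in range(X.shape[1]):
        deltas = []
        for _ in range(n_repeats):
            perm = rng.permutation(len(y))
            X_perm = X.copy()
            X_perm[:, fi] = X[perm, fi]
            mse = float(np.mean((model.estimator.predict(X_perm) - y) ** 2))
            deltas.append(mse - base_mse)
        raw[fi] = np.mean(deltas)
    return ImportanceReport(
        "PERMUTATION", model.config.family.name, tuple(table.feature_names),
        raw, _normalize(raw),
    )


def lofo_importance(
    config: ModelConfig,
    table: FeatureTable,
    eval_table: FeatureTable,
) -> ImportanceReport:
    """Leave-one-feature-out: MSE(without feature) - MSE(with all features).

    Positive values mean the feature helps.  A feature with a perfectly
    redundant duplicate scores ~0 even if the underlying signal is strong.
    """
    full_model = fit_on(config, table)
    full_mse = compute_metrics(predict_raw(full_model, eval_table), eval_table.y).mse
    raw = np.zeros(len(table.feature_names))
    for fi, fname in enumerate(table.feature_names):
        reduced = tuple(f for f in table.feature_names if f != fname)
        model = fit_on(config, table.select(reduced))
        mse = compute_metrics(
            predict_raw(model, eval_table.select(reduced)), eval_table.y
        ).mse
        raw[fi] = mse - full_mse
    return ImportanceReport(
        "LOFO_MSE", config.family.name, tuple(table.feature_names), raw, _normalize(raw)
    )


def shapley_importance(
    model: TrainedModel,
    table: FeatureTable,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Shapley-value importance; substituted by permutation importance.

    No Shapley engine is bundled, so the permutation mechanism stands in;
    the substitution is recorded in the report's note.
    """
    report = permutation_importance(model, table, n_repeats=n_repeats, seed=seed)
    return ImportanceReport(
        "SHAPLEY", report.family, report.features, report.raw, report.normalized,
        note="Shapley engine unavailable; permutation importance substituted",
    )


# ---------------------------------------------------------------------------
# Benchmark and ablation


@dataclass
class BenchmarkReport:
    """Per family x {with LIE, without LIE}: repetition-aggregated metrics."""

    results: dict[tuple[str, bool], RepetitionReport] = field(default_factory=dict)
    failures: dict[tuple[str, bool], str] = field(default_factory=dict)
    scatter: dict[tuple[str, bool], pd.DataFrame] = field(default_factory=dict)

    def metric(self, family: ModelFamily | str, with_lie: bool, split: str, name: str) -> float:
        fam = family.name if isinstance(family, ModelFamily) else family
        return getattr(self.results[(fam, with_lie)].mean[split], name)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (fam, with_lie), rep in self.results.items():
            for split, m in rep.mean.items():
                s = rep.std[split]
                rows.append(
                    {
                        "family": fam,
                        "with_lie": with_lie,
                        "split": split,
                        "r2_mean": m.r2, "r2_std": s.r2,
                        "mse_mean": m.mse, "mse_std": s.mse,
                        "mae_mean": m.mae, "mae_std": s.mae,
                    }
                )
        return pd.DataFrame(rows)

    def ranked(self, split: str = "validation", with_lie: bool = True) -> list[str]:
        cells = [
            (fam, rep.mean[split].r2)
            for (fam, flag), rep in self.results.items()
            if flag is with_lie and split in rep.mean
        ]
        return [fam for fam, _ in sorted(cells, key=lambda c: -c[1])]


def run_benchmark(
    table: FeatureTable,
    validation_table: FeatureTable | None = None,
    families: tuple[ModelFamily, ...] = tuple(ModelFamily),
    ablate_lie: bool = False,
    n_reps: int = 10,
    seed: int = 0,
) -> BenchmarkReport:
    """Run the repetition protocol for each family (optionally also LIE-ablated).

    A failing family is recorded and skipped; the others continue.  For every
    trained cell the last repetition's (predicted, actual) pairs on the test
    set are kept for density-scatter plotting.
    """
    report = BenchmarkReport()
    variants = [True, False] if ablate_lie else [True]
    for with_lie in variants:
        if with_lie:
            sub = table
            val = validation_table
        else:
            kept = tuple(f for f in table.feature_names if f not in LIE_FEATURES)
            sub = table.select(kept)
            val = validation_table.select(kept) if validation_table is not None else None
        for family in families:
            cfg = ModelConfig(family, seed=seed, use_lie_features=with_lie)
            try:
                rep = run_repetitions(
                    cfg, sub, n_reps=n_reps, validation_table=val, seed=seed
                )
            except Exception as exc:  # isolate the failing family
                logger.exception("family %s failed", family.name)
                report.failures[(family.name, with_lie)] = str(exc)
                continue
            report.results[(family.name, with_lie)] = rep
            if rep.last_model is not None:
                model = rep.last_model
                preds = predict_raw(model, val if val is not None else sub)
                actual = (val if val is not None else sub).y
                report.scatter[(family.name, with_lie)] = pd.DataFrame(
                    {"predicted": preds, "actual": actual}
                )
    return report


def fcnn_sweep(
    table: FeatureTable,
    validation_table: FeatureTable | None,
    architectures: tuple[tuple[int, ...], ...] = ((), (12,), (12, 6), (12, 6, 3)),
    dropouts: tuple[float, ...] = (0.0, 0.01, 0.05, 0.3),
    activations: tuple[str, ...] = ("relu",),
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Grid over FCNN architecture x dropout x activation; one seeded cell each."""
    if not (architectures and dropouts and activations):
        raise ValueError("grids must be non-empty")
    rows = []
    for arch in architectures:
        for p in dropouts:
            for act in activations:
                cfg = ModelConfig(
                    ModelFamily.FCNN,
                    {"hidden_sizes": tuple(arch), "dropout_rate": p, "activation": act},
                    seed=seed,
                )
                rep = run_repetitions(
                    cfg, table, n_reps=n_reps, validation_table=validation_table, seed=seed
                )
                row = {
                    "architecture": "-".join(map(str, (len(table.feature_names), *arch, 1))),
                    "hidden_sizes": arch,
                    "dropout": p,
                    "activation": act,
                }
                for split, m in rep.mean.items():
                    row[f"{split}_r2"] = m.r2
                    row[f"{split}_mse"] = m.mse
                    row[f"{split}_mae"] = m.mae
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ReductionCurve:
    points: pd.DataFrame  # columns: k, fraction, n_rows, r2, mse, mae (validation)


def data_reduction_curve(
    config: ModelConfig,
    table: FeatureTable,
    validation_table: FeatureTable,
    k_values: tuple[int, ...] = (1, 2, 5, 10, 20, 50, 100),
    seed: int = 0,
    min_rows: int = 50,
) -> ReductionCurve:
    """Every-kth-row subsampling of the training data with full retraining.

    Because MD-derived rows are time-ordered within each trajectory, taking
    every kth row thins time-correlated (partially redundant) frames first.
    Points whose subsample falls below ``min_rows`` are skipped and logged.
    """
    rows = []
    for k in sorted(set(int(k) for k in k_values)):
        sub = subsample_every_kth(table, k)
        if len(sub) < min_rows:
            logger.warning("skipping k=%d: only %d rows", k, len(sub))
            continue
        cfg = ModelConfig(config.family, dict(config.hyperparameters), seed=seed + k)
        model = fit_on(cfg, sub)
        m = compute_metrics(predict_raw(model, validation_table), validation_table.y)
        rows.append(
            {"k": k, "fraction": 1.0 / k, "n_rows": len(sub),
             "r2": m.r2, "mse": m.mse, "mae": m.mae}
        )
    return ReductionCurve(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Trajectory-level evaluation


@dataclass
class TrajectoryEval:
    per_trajectory: pd.DataFrame
    pearson_r: float
    r2: float
    mae: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        logger.warning("constant vector in correlation; Pearson r undefined (NaN)")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def trajectory_mean_eval(
    model: TrainedModel,
    table: FeatureTable,
    trajectory_key: str = "system_id",
) -> TrajectoryEval:
    """Compare per-trajectory mean predictions against mean actual energies."""
    groups = table.df[trajectory_key]
    if groups.nunique() < 2:
        raise ValueError("need >= 2 trajectories")
    preds = predict_raw(model, table)
    df = pd.DataFrame(
        {trajectory_key: groups, "predicted": preds, "actual": table.y}
    ).groupby(trajectory_key, sort=True).mean().reset_index()
    m = compute_metrics(df["predicted"].to_numpy(), df["actual"].to_numpy())
    return TrajectoryEval(df, _pearson(df["predicted"].to_numpy(), df["actual"].to_numpy()),
                          m.r2, m.mae)


@dataclass
class FirstFrameScreen:
    per_trajectory: pd.DataFrame  # frame0 prediction vs trajectory-mean actual
    pearson_r: float
    r2: float
    mae: float
    threshold: float


def first_frame_screen(
    model: TrainedModel,
    table: FeatureTable,
    threshold: float = 0.0,
    trajectory_key: str = "system_id",
) -> FirstFrameScreen:
    """Rank trajectories by the frame-0 prediction against mean actual energy.

    Trajectories are partitioned into strong (frame-0 prediction below the
    energy threshold, i.e. more favourable) and weak binders; trajectories
    without a frame 0 are skipped with a log message.
    """
    df = table.df
    rows = []
    for key, grp in df.groupby(trajectory_key, sort=True):
        first = grp[grp["frame_index"] == 0]
        if first.empty:
            logger.warning("trajectory %s has no frame 0; skipped", key)
            continue
        pos = df.index.get_indexer(first.index[:1])
        pred0 = float(predict_raw(model, table.take(pos))[0])
        rows.append(
            {
                trajectory_key: key,
                "frame0_predicted": pred0,
                "mean_actual": float(grp[table.target_column].mean()),
                "classified": "strong" if pred0 <= threshold else "weak",
            }
        )
    out = pd.DataFrame(rows)
    if len(out) < 2:
        raise ValueError("need >= 2 trajectories with a frame 0")
    m = compute_metrics(out["frame0_predicted"].to_numpy(), out["mean_actual"].to_numpy())
    return FirstFrameScreen(
        out,
        _pearson(out["frame0_predicted"].to_numpy(), out["mean_actual"].to_numpy()),
        m.r2, m.mae, threshold,
    )
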