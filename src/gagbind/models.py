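"""The eight regression families with a uniform train/predict contract.

Each family is configured, by default, to the winning hyperparameters of the
benchmarking protocol's grid search:

* ElasticNet: alpha = 1.0, l1_ratio = 0.5
* Linear regression: ordinary least squares, no regularisation
* LinearSVR: C = 1.0, epsilon = 0.1, max_iter = 10000
* RBFSampler + LinearSVR: 100 random Fourier components, gamma = 1/n_features
* LightGBM: 200 rounds, depth 8, learning rate 0.1, row/column subsample 0.8
* Histogram gradient boosting: 200 iterations, depth 6, lr 0.1, L2 = 0.1
* Random forest: 200 trees, depth 30, min split 2, min leaf 1, 'sqrt' features
* FCNN: no hidden layers, dropout 0.01, ReLU, Adam (lr 1e-3, weight decay
  1e-4), early stopping with patience 15, plateau LR reduction

Two uncertainty procedures are provided: Monte Carlo dropout for the FCNN
(30 stochastic forward passes) and repeated k-fold cross-validation
prediction spread for any family (30 rounds of 10-fold CV by default).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from lightgbm import LGBMRegressor
from sklearn.ensemble import HistGradientBoostingRegressor, RandomForestRegressor
from sklearn.kernel_approximation import RBFSampler
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.pipeline import Pipeline
from sklearn.svm import LinearSVR

from gagbind.dataset import (
    FeatureTable,
    Metrics,
    ScalerParams,
    compute_metrics,
    split_random,
    zscore_apply,
    zscore_fit,
)
from gagbind.nn import FCNNConfig, FCNNRegressor

warnings.filterwarnings(
    "ignore", message="X does not have valid feature names", category=UserWarning
)

ARCHIVE_SCHEMA_VERSION = 1

MIN_TRAIN_ROWS = 50


class ModelFamily(enum.Enum):
    ELASTIC_NET = "ELASTIC_NET"
    LINEAR_REGRESSION = "LINEAR_REGRESSION"
    LINEAR_SVR = "LINEAR_SVR"
    RBF_SAMPLER_LINEAR_SVR = "RBF_SAMPLER_LINEAR_SVR"
    GRADIENT_BOOST_TREES = "GRADIENT_BOOST_TREES"
    HIST_GRADIENT_BOOST = "HIST_GRADIENT_BOOST"
    RANDOM_FOREST = "RANDOM_FOREST"
    FCNN = "FCNN"


LINEAR_FAMILIES = (
    ModelFamily.ELASTIC_NET,
    ModelFamily.LINEAR_REGRESSION,
    ModelFamily.LINEAR_SVR,
)

DEFAULT_HYPERPARAMETERS: dict[ModelFamily, dict] = {
    ModelFamily.ELASTIC_NET: {"alpha": 1.0, "l1_ratio": 0.5},
    ModelFamily.LINEAR_REGRESSION: {},
    ModelFamily.LINEAR_SVR: {"C": 1.0, "epsilon": 0.1, "max_iter": 10000},
    ModelFamily.RBF_SAMPLER_LINEAR_SVR: {
        "C": 1.0,
        "epsilon": 0.1,
        "max_iter": 10000,
        "n_components": 100,
        "gamma": None,  # None -> 1 / n_features at fit time
    },
    ModelFamily.GRADIENT_BOOST_TREES: {
        "n_estimators": 200,
        "max_depth": 8,
        "learning_rate": 0.1,
        "subsample": 0.8,
        "colsample_bytree": 0.8,
    },
    ModelFamily.HIST_GRADIENT_BOOST: {
        "max_iter": 200,
        "max_depth": 6,
        "learning_rate": 0.1,
        "l2_regularization": 0.1,
    },
    ModelFamily.RANDOM_FOREST: {
        "n_estimators": 200,
        "max_depth": 30,
        "min_samples_split": 2,
        "min_samples_leaf": 1,
        "max_features": "sqrt",
    },
    ModelFamily.FCNN: {
        "hidden_sizes": (),
        "dropout_rate": 0.01,
        "activation": "relu",
        "learning_rate": 1e-3,
        "weight_decay": 1e-4,
        "batch_size": 256,
        "max_epochs": 200,
        "early_stop_patience": 15,
        "plateau_factor": 0.5,
        "plateau_patience": 7,
        "val_fraction": 0.1,
        "mc_passes": 30,
    },
}

#: The hyperparameter grids that were searched; defaults above are the winners.
GRID_PRESETS: dict[ModelFamily, dict] = {
    ModelFamily.GRADIENT_BOOST_TREES: {
        "n_estimators": [100, 200],
        "max_depth": [4, 6, 8],
        "learning_rate": [0.05, 0.1],
        "subsample": [0.8],
        "colsample_bytree": [0.8],
    },
    ModelFamily.HIST_GRADIENT_BOOST: {
        "max_iter": [100, 200],
        "max_depth": [4, 6],
        "learning_rate": [0.05, 0.1],
        "l2_regularization": [0.0, 0.1],
    },
    ModelFamily.RANDOM_FOREST: {
        "n_estimators": [50, 100, 200],
        "max_depth": [10, 20, 30, None],
        "min_samples_split": [2, 5, 10],
        "min_samples_leaf": [1, 2, 4],
        "max_features": ["sqrt", "log2", None],
    },
    ModelFamily.FCNN: {
        "hidden_sizes": [(), (12,), (12, 6), (12, 6, 3)],
        "dropout_rate": [0.0, 0.01, 0.05, 0.3],
        "activation": ["relu", "elu", "gelu", "leaky_relu", "sigmoid", "tanh"],
    },
}


@dataclass
class ModelConfig:
    """A model-family specification plus its hyperparameter overrides."""

    family: ModelFamily
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0
    use_lie_features: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.family, str):
            self.family = ModelFamily[self.family]
        allowed = set(DEFAULT_HYPERPARAMETERS[self.family])
        unknown = set(self.hyperparameters) - allowed
        if unknown:
            raise ValueError(
                f"unknown hyperparameter(s) for {self.family.name}: {sorted(unknown)}"
            )

    def resolved(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        return params


@dataclass
class TrainedModel:
    """A fitted estimator with its config, scaler and feature schema."""

    estimator: object
    config: ModelConfig
    feature_names: tuple[str, ...]
    scaler: ScalerParams | None = None
    training_log: dict = field(default_factory=dict)


def make_estimator(config: ModelConfig, n_features: int):
    """Instantiate the underlying estimator for a family."""
    p = config.resolved()
    fam = config.family
    if fam is ModelFamily.ELASTIC_NET:
        return ElasticNet(alpha=p["alpha"], l1_ratio=p["l1_ratio"], random_state=config.seed)
    if fam is ModelFamily.LINEAR_REGRESSION:
        return LinearRegression()
    if fam is ModelFamily.LINEAR_SVR:
        return LinearSVR(
            C=p["C"], epsilon=p["epsilon"], max_iter=p["max_iter"], random_state=config.seed
        )
    if fam is ModelFamily.RBF_SAMPLER_LINEAR_SVR:
        gamma = p["gamma"] if p["gamma"] is not None else 1.0 / n_features
        return Pipeline(
            [
                (
                    "rbf",
                    RBFSampler(
                        gamma=gamma, n_components=p["n_components"], random_state=config.seed
                    ),
                ),
                (
                    "svr",
                    LinearSVR(
                        C=p["C"],
                        epsilon=p["epsilon"],
                        max_iter=p["max_iter"],
                        random_state=config.seed,
                    ),
                ),
            ]
        )
    if fam is ModelFamily.GRADIENT_BOOST_TREES:
        return LGBMRegressor(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            subsample=p["subsample"],
            subsample_freq=1,
            colsample_bytree=p["colsample_bytree"],
            random_state=config.seed,
            n_jobs=1,
            verbose=-1,
        )
    if fam is ModelFamily.HIST_GRADIENT_BOOST:
        return HistGradientBoostingRegressor(
            max_iter=p["max_iter"],
            max_depth=p["max_depth"],
            learning_rate=p["learning_rate"],
            l2_regularization=p["l2_regularization"],
            random_state=config.seed,
        )
    if fam is ModelFamily.RANDOM_FOREST:
        return RandomForestRegressor(
            n_estimators=p["n_estimators"],
            max_depth=p["max_depth"],
            min_samples_split=p["min_samples_split"],
            min_samples_leaf=p["min_samples_leaf"],
            max_features=p["max_features"],
            random_state=config.seed,
            n_jobs=1,
        )
    if fam is ModelFamily.FCNN:
        fcfg = FCNNConfig(
            hidden_sizes=tuple(p["hidden_sizes"]),
            dropout_rate=p["dropout_rate"],
            activation=p["activation"],
            learning_rate=p["learning_rate"],
            weight_decay=p["weight_decay"],
            batch_size=p["batch_size"],
            max_epochs=p["max_epochs"],
            early_stop_patience=p["early_stop_patience"],
            plateau_factor=p["plateau_factor"],
            plateau_patience=p["plateau_patience"],
            val_fraction=p["val_fraction"],
            mc_passes=p["mc_passes"],
            seed=config.seed,
        )
        return FCNNRegressor(fcfg)
    raise ValueError(f"unhandled family {fam}")


def train(
    config: ModelConfig,
    train_table: FeatureTable,
    scaler: ScalerParams | None = None,
) -> TrainedModel:
    """Fit one model on an (already scaled) training table.

    ``scaler`` is carried along purely so the trained model can later be
    applied to raw tables; it is not applied here.
    """
    if len(train_table) < MIN_TRAIN_ROWS:
        raise ValueError(
            f"need >= {MIN_TRAIN_ROWS} training rows, got {len(train_table)}"
        )
    est = make_estimator(config, n_features=len(train_table.feature_names))
    with warnings.catch_warnings():
        # LinearSVR under its iteration cap returns a usable partial model
        warnings.filterwarnings("always", category=UserWarning)
        est.fit(train_table.X, train_table.y)
    log = {}
    if isinstance(est, FCNNRegressor):
        log = {"epochs": len(est.history_.get("train_loss", []))}
    return TrainedModel(est, config, tuple(train_table.feature_names), scaler, log)


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict target values (kcal/mol) for each row; deterministic."""
    if tuple(table.feature_names) != model.feature_names:
        diff = set(table.feature_names) ^ set(model.feature_names)
        raise ValueError(f"feature schema mismatch; symmetric difference: {sorted(diff)}")
    return np.asarray(model.estimator.predict(table.X), dtype=float)


def mc_dropout_predict(
    model: TrainedModel,
    table: FeatureTable,
    n_passes: int = 30,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (mean, std) over stochastic dropout forward passes (FCNN only)."""
    if not isinstance(model.estimator, FCNNRegressor):
        raise ValueError("MC dropout is only defined for the FCNN family")
    if tuple(table.feature_names) != model.feature_names:
        raise ValueError("feature schema mismatch")
    return model.estimator.mc_predict(table.X, n_passes=n_passes, seed=seed)


def repeated_cv_prediction_std(
    config: ModelConfig,
    table: FeatureTable,
    rounds: int = 30,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Per-row std of out-of-fold predictions over repeated k-fold CV.

    Each round draws a fresh seeded fold partition; each row is predicted by
    the model trained on the other folds, and the spread of a row's
    out-of-fold predictions across rounds is its uncertainty estimate.
    """
    n = len(table)
    if n < folds:
        raise ValueError(f"table must have at least {folds} rows")
    preds = np.empty((rounds, n))
    for r in range(rounds):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, folds)):
            fold_of[chunk] = f
        for f in range(folds):
            held = fold_of == f
            sub = table.take(np.flatnonzero(~held))
            cfg = ModelConfig(config.family, dict(config.hyperparameters),
                              seed=seed + r, use_lie_features=config.use_lie_features)
            model = train(cfg, sub)
            preds[r, held] = predict(model, table.take(np.flatnonzero(held)))
    return preds.std(axis=0)


@dataclass
class RepetitionReport:
    """Mean +/- std metrics over independently re-split, re-trained repetitions."""

    mean: dict[str, Metrics]
    std: dict[str, Metrics]
    per_rep: dict[str, list[Metrics]]
    last_model: TrainedModel | None = None

    def summary(self) -> dict:
        return {
            split: {
                "r2_mean": self.mean[split].r2,
                "r2_std": self.std[split].r2,
                "mse_mean": self.mean[split].mse,
                "mse_std": self.std[split].mse,
                "mae_mean": self.mean[split].mae,
                "mae_std": self.std[split].mae,
            }
            for split in self.mean
        }


def _aggregate(metrics_list: list[Metrics]) -> tuple[Metrics, Metrics]:
    arr = np.array([[m.r2, m.mse, m.mae] for m in metrics_list], dtype=float)
    mean = arr.mean(axis=0)
    std = arr.std(axis=0) if len(metrics_list) > 1 else np.zeros(3)
    return Metrics(*mean), Metrics(*std)


def run_repetitions(
    config: ModelConfig,
    table: FeatureTable,
    n_reps: int = 10,
    validation_table: FeatureTable | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> RepetitionReport:
    """Train ``n_reps`` independent models, each on a freshly regenerated split.

    Every repetition draws a new random 80/20 train/test split, fits the
    scaler on that repetition's training rows only, trains under a fresh
    seed, and evaluates on train, test and (if given) the group-held-out
    validation table.  Metrics are aggregated as mean and std.
    """
    sets: dict[str, list[Metrics]] = {"train": [], "test": []}
    if validation_table is not None:
        sets["validation"] = []
    last_model = None
    for rep in range(n_reps):
        rep_seed = seed + rep
        train_raw, test_raw = split_random(table, test_fraction, seed=rep_seed)
        scaler = zscore_fit(train_raw)
        train_s = zscore_apply(train_raw, scaler)
        test_s = zscore_apply(test_raw, scaler)
        cfg = ModelConfig(config.family, dict(config.hyperparameters),
                          seed=rep_seed, use_lie_features=config.use_lie_features)
        model = train(cfg, train_s, scaler=scaler)
        sets["train"].append(compute_metrics(predict(model, train_s), train_s.y))
        sets["test"].append(compute_metrics(predict(model, test_s), test_s.y))
        if validation_table is not None:
            val_s = zscore_apply(validation_table, scaler)
            sets["validation"].append(compute_metrics(predict(model, val_s), val_s.y))
        last_model = model
    mean = {k: _aggregate(v)[0] for k, v in sets.items()}
    std = {k: _aggregate(v)[1] for k, v in sets.items()}
    return RepetitionReport(mean, std, sets, last_model)


# ---------------------------------------------------------------------------
# Persistence


def save_model(model: TrainedModel, path) -> None:
    """Save fitted state + config + scaler as a versioned archive."""
    payload = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "family": model.config.family.name,
        "hyperparameters": model.config.hyperparameters,
        "seed": model.config.seed,
        "use_lie_features": model.config.use_lie_features,
        "feature_names": list(model.feature_names),
        "scaler": model.scaler.to_dict() if model.scaler else None,
        "estimator": model.estimator,
        "training_log": model.training_log,
    }
    joblib.dump(payload, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("schema_version")
    if version != ARCHIVE_SCHEMA_VERSION:
        raise ValueError(
            f"refusing to load archive with schema version {version!r} "
            f"(expected {ARCHIVE_SCHEMA_VERSION})"
        )
    config = ModelConfig(
        family=ModelFamily[payload["family"]],
        hyperparameters=payload["hyperparameters"],
        seed=payload["seed"],
        use_lie_features=payload["use_lie_features"],
    )
    scaler = ScalerParams.from_dict(payload["scaler"]) if payload["scaler"] else None
    return TrainedModel(
        payload["estimator"], config, tuple(payload["feature_names"]),
        scaler, payload["training_log"],
    )
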