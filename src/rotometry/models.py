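"""Train/test splitting and the five regression algorithms.

The five algorithms compared for angle regression, with tuned reference
hyperparameters as defaults:

========================================  ==========================================
algorithm                                 defaults
========================================  ==========================================
``ordinary_least_squares``                (no hyperparameters)
``elastic_net``                           alpha 1e-5, l1_ratio 0.889
``kernel_support_vector_regression``      RBF kernel, C 10.0, gamma 0.0046
``random_forest``                         squared_error, max_depth 6, 10 estimators
``gradient_boosted_trees``                MAE objective, learning_rate 0.076,
                                          max_depth 8 (LightGBM)
========================================  ==========================================

Hyperparameters not listed fall back to the underlying implementation's
defaults (recorded verbatim in run manifests), except ``elastic_net``'s
``max_iter`` which is raised to 50,000 so the coordinate-descent solver
reaches its own tolerance at the near-unpenalized alpha on the raw feature
scale. Features are used unscaled — the reference gamma/alpha values
assume the raw feature ranges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.svm import SVR

from .errors import SchemaError, SplitError, UnsupportedModelError
from .features import FEATURE_NAMES

ALGORITHMS: tuple[str, ...] = (
    "ordinary_least_squares",
    "elastic_net",
    "kernel_support_vector_regression",
    "random_forest",
    "gradient_boosted_trees",
)

#: Short aliases accepted anywhere an algorithm name is.
ALGORITHM_ALIASES: dict[str, str] = {
    "ols": "ordinary_least_squares",
    "linear": "ordinary_least_squares",
    "enet": "elastic_net",
    "svr": "kernel_support_vector_regression",
    "svm": "kernel_support_vector_regression",
    "rf": "random_forest",
    "gbt": "gradient_boosted_trees",
    "lightgbm": "gradient_boosted_trees",
}

TREE_ENSEMBLES = ("random_forest", "gradient_boosted_trees")

DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "ordinary_least_squares": {},
    "elastic_net": {"alpha": 1e-5, "l1_ratio": 0.889, "max_iter": 50_000},
    "kernel_support_vector_regression": {"kernel": "rbf", "C": 10.0, "gamma": 0.0046},
    "random_forest": {"criterion": "squared_error", "max_depth": 6, "n_estimators": 10},
    "gradient_boosted_trees": {
        "objective": "regression_l1",
        "learning_rate": 0.076,
        "max_depth": 8,
    },
}


def canonical_algorithm(name: str) -> str:
    name = ALGORITHM_ALIASES.get(name.lower(), name.lower())
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {name!r}; choose from {ALGORITHMS}")
    return name


@dataclass(frozen=True)
class ModelSpec:
    """An algorithm choice plus its hyperparameters and seed.

    ``hyperparameters`` override the reference defaults key-by-key.
    """

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "algorithm", canonical_algorithm(self.algorithm))

    def resolved_hyperparameters(self) -> dict:
        hp = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        hp.update(self.hyperparameters)
        return hp


@dataclass
class SplitDataset:
    """An 80/20-style partition of a feature table."""

    train: pd.DataFrame
    test: pd.DataFrame
    split_seed: int
    split_unit: str

    def __post_init__(self) -> None:
        if len(self.train) == 0 or len(self.test) == 0:
            raise SplitError("both partitions must be nonempty")


def split(
    rows: pd.DataFrame,
    fraction_test: float = 0.2,
    seed: int = 0,
    unit: str = "frame",
) -> SplitDataset:
    """Random, reproducible train/test partition of a feature table.

    ``unit`` is ``frame`` (each row independently), ``clip`` (whole clips
    stay together) or ``subject`` (whole subjects stay together). Group
    units avoid leaking near-duplicate neighboring frames across the split.
    """
    if not (0.0 < fraction_test < 1.0):
        raise SplitError("fraction_test must be in (0, 1)")
    if len(rows) < 2:
        raise SplitError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    if unit == "frame":
        n = len(rows)
        n_test = int(round(n * fraction_test))
        if n_test == 0 or n_test == n:
            raise SplitError("fraction_test leaves a partition empty")
        perm = rng.permutation(n)
        test_idx = np.sort(perm[:n_test])
        train_idx = np.sort(perm[n_test:])
        return SplitDataset(
            train=rows.iloc[train_idx].reset_index(drop=True),
            test=rows.iloc[test_idx].reset_index(drop=True),
            split_seed=seed,
            split_unit=unit,
        )
    if unit in ("clip", "subject"):
        if unit == "clip":
            keys = rows[["subject_id", "clip_id"]].astype(str).agg("/".join, axis=1)
        else:
            keys = rows["subject_id"].astype(str)
        uniq = keys.unique()
        n_test_groups = int(round(len(uniq) * fraction_test))
        if n_test_groups == 0 or n_test_groups == len(uniq):
            raise SplitError(f"too few {unit}s ({len(uniq)}) for fraction {fraction_test}")
        perm = rng.permutation(len(uniq))
        test_groups = set(uniq[perm[:n_test_groups]])
        mask = keys.isin(test_groups).to_numpy()
        return SplitDataset(
            train=rows.loc[~mask].reset_index(drop=True),
            test=rows.loc[mask].reset_index(drop=True),
            split_seed=seed,
            split_unit=unit,
        )
    raise SplitError(f"unknown split unit {unit!r}")


@dataclass
class FittedModel:
    """A trained regressor together with its spec and feature order."""

    spec: ModelSpec
    estimator: object
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        """Predicted angle in degrees, one finite value per row."""
        X = design_matrix(rows, self.feature_names)
        if len(X) == 0:
            return np.empty(0)
        pred = np.asarray(self.estimator.predict(X), dtype=float)
        if not np.all(np.isfinite(pred)):
            raise SchemaError("model produced non-finite predictions")
        return pred

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        joblib.dump(
            {
                "format": "rotometry-model",
                "version": 1,
                "spec": self.spec,
                "feature_names": self.feature_names,
                "estimator": self.estimator,
            },
            path,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        payload = joblib.load(path)
        if not isinstance(payload, dict) or payload.get("format") != "rotometry-model":
            raise SchemaError(f"{path} is not a rotometry model file")
        return cls(
            spec=payload["spec"],
            estimator=payload["estimator"],
            feature_names=tuple(payload["feature_names"]),
        )


def design_matrix(
    rows: pd.DataFrame, feature_names: Sequence[str] = FEATURE_NAMES
) -> pd.DataFrame:
    missing = [c for c in feature_names if c not in rows.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s) {missing}")
    return rows[list(feature_names)]


def _build_estimator(spec: ModelSpec):
    hp = spec.resolved_hyperparameters()
    algo = spec.algorithm
    if algo == "ordinary_least_squares":
        return LinearRegression(**hp)
    if algo == "elastic_net":
        return ElasticNet(random_state=spec.seed, **hp)
    if algo == "kernel_support_vector_regression":
        return SVR(**hp)
    if algo == "random_forest":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **hp)
    if algo == "gradient_boosted_trees":
        # single thread + fixed seed => bit-reproducible boosting
        return LGBMRegressor(
            random_state=spec.seed, n_jobs=1, verbose=-1, **hp
        )
    raise UnsupportedModelError(algo)


def fit(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit one algorithm on a feature table with a ``true_angle_deg`` column."""
    if len(train) == 0:
        raise SchemaError("training table is empty")
    if "true_angle_deg" not in train.columns:
        raise SchemaError("training table lacks a true_angle_deg column")
    X = design_matrix(train)
    y = train["true_angle_deg"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        warnings.warn(
            "constant target column: the fitted model will predict the constant",
            RuntimeWarning,
            stacklevel=2,
        )
    est = _build_estimator(spec)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est)


def predict(model: FittedModel, rows: pd.DataFrame) -> np.ndarray:
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(rows)


def is_tree_ensemble(model: FittedModel) -> bool:
    return model.spec.algorithm in TREE_ENSEMBLES
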