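"""Model evaluation: agreement metrics, residual tables, attributions.

The evaluation battery mirrors how markerless joint-angle estimators are
validated against a gold standard: Pearson correlation and mean absolute
error between predicted and true angles on held-out frames, residuals
(actual − predicted) summarized per design angle, the feature/angle
correlation structure, and two model-interpretation views for tree
ensembles — split-gain feature importance normalized per tree, and Shapley
additive (SHAP) per-prediction attributions.

SHAP values are exact here, not sampled: LightGBM models use the built-in
path-dependent TreeSHAP; other ensembles use interventional Shapley values
computed by full enumeration of all 2^7 feature coalitions against a
background sample, which is cheap with seven features. Both satisfy local
accuracy (base value + contributions = prediction) to machine precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, UnsupportedModelError
from .features import FEATURE_NAMES
from .models import FittedModel, design_matrix, is_tree_ensemble


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SchemaError("pearson expects two equal-length 1-D vectors")
    if len(x) < 2:
        raise SchemaError("pearson needs at least 2 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(xd @ xd)
    sy = float(yd @ yd)
    if sx == 0.0 or sy == 0.0:
        raise SchemaError("correlation undefined for a zero-variance vector")
    return float(np.clip((xd @ yd) / math.sqrt(sx * sy), -1.0, 1.0))


def mae(true, pred) -> float:
    """Mean absolute error (degrees when inputs are degrees)."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape or true.ndim != 1 or len(true) == 0:
        raise SchemaError("mae expects two equal-length nonempty 1-D vectors")
    return float(np.mean(np.abs(true - pred)))


def residual_by_angle(true, pred, nominal) -> pd.DataFrame:
    """Mean and sample SD of the residual (actual − predicted) per design angle.

    Returns a frame indexed by ascending nominal angle with columns
    ``mean_deg``, ``sd_deg``, ``n`` and ``single`` (flagging size-1 groups,
    whose SD is reported as 0).
    """
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    nominal = np.asarray(nominal, dtype=float)
    if not (true.shape == pred.shape == nominal.shape) or true.ndim != 1:
        raise SchemaError("residual_by_angle expects three aligned 1-D vectors")
    df = pd.DataFrame({"nominal": nominal, "residual": true - pred})
    out = (
        df.groupby("nominal")["residual"]
        .agg(mean_deg="mean", sd_deg=lambda s: s.std(ddof=1), n="size")
        .sort_index()
    )
    out["single"] = out["n"] == 1
    out.loc[out["single"], "sd_deg"] = 0.0
    out["n"] = out["n"].astype(int)
    out.index.name = "nominal_angle_deg"
    return out


def feature_correlation_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    """8×8 Pearson correlation matrix over the 7 features plus the angle.

    Constant columns yield NaN off-diagonal entries (flagged undefined);
    the diagonal is exactly 1.
    """
    cols = list(FEATURE_NAMES) + ["true_angle_deg"]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s) {missing}")
    if len(rows) < 2:
        raise SchemaError("need at least 2 rows for a correlation matrix")
    mat = rows[cols].corr(method="pearson")
    np.fill_diagonal(mat.values, 1.0)
    return mat


# ------------------------------------------------------------- importance


def tree_feature_importance(model: FittedModel) -> pd.Series:
    """Split-gain importance, normalized within each tree then averaged.

    For every tree in the ensemble the gain attributed to each feature is
    divided by the tree's total gain, and these per-tree shares are averaged
    over all trees — so a feature's importance is its mean share of the
    splits' improvement, and the values sum to 1. Trees without splits
    contribute nothing.
    """
    if not is_tree_ensemble(model):
        raise UnsupportedModelError(
            f"feature importance requires a tree ensemble, got {model.spec.algorithm}"
        )
    names = list(model.feature_names)
    if model.spec.algorithm == "gradient_boosted_trees":
        tree_df = model.estimator.booster_.trees_to_dataframe()
        splits = tree_df[tree_df["split_feature"].notna()]
        per_tree = splits.pivot_table(
            index="tree_index",
            columns="split_feature",
            values="split_gain",
            aggfunc="sum",
            fill_value=0.0,
        ).reindex(columns=names, fill_value=0.0)
    else:  # random forest
        shares = []
        for tree in model.estimator.estimators_:
            imp = tree.feature_importances_  # already normalized per tree
            if imp.sum() > 0:
                shares.append(imp)
        if not shares:
            raise SchemaError("no tree in the ensemble contains a split")
        mean = np.mean(shares, axis=0)
        mean = mean / mean.sum()
        return pd.Series(mean, index=names, name="importance")
    totals = per_tree.sum(axis=1)
    per_tree = per_tree.loc[totals > 0].div(totals[totals > 0], axis=0)
    if per_tree.empty:
        raise SchemaError("no tree in the ensemble contains a split")
    mean = per_tree.mean(axis=0)
    mean = mean / mean.sum()
    return pd.Series(mean.to_numpy(), index=names, name="importance")


# ------------------------------------------------------------------ SHAP


@dataclass
class ShapSummary:
    """Per-row, per-feature signed contributions plus the base value.

    ``values`` has one column per feature (degrees); ``base_values`` is the
    expected model output the contributions are measured against. For every
    row, ``base + Σ contributions`` equals the model prediction (local
    accuracy).
    """

    values: pd.DataFrame
    base_values: np.ndarray

    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0).rename("mean_abs_shap")

    def local_accuracy_gap(self, predictions: np.ndarray) -> np.ndarray:
        return np.asarray(predictions) - (
            self.base_values + self.values.to_numpy().sum(axis=1)
        )


def shap_attributions(
    model: FittedModel,
    rows: pd.DataFrame,
    background: pd.DataFrame | None = None,
    max_background: int = 64,
    seed: int = 0,
) -> ShapSummary:
    """Exact Shapley additive attributions for a tree-ensemble model.

    LightGBM models use the built-in exact TreeSHAP (path-dependent; no
    background needed). Other ensembles use interventional Shapley values
    with the empirical background distribution: all 2^7 coalitions are
    enumerated, so no sampling error is introduced. ``background`` defaults
    to ``rows`` (subsampled to ``max_background``).
    """
    if not is_tree_ensemble(model):
        raise UnsupportedModelError(
            f"SHAP attributions require a tree ensemble, got {model.spec.algorithm}"
        )
    X = design_matrix(rows, model.feature_names)
    names = list(model.feature_names)
    if model.spec.algorithm == "gradient_boosted_trees":
        contrib = model.estimator.booster_.predict(X, pred_contrib=True)
        return ShapSummary(
            values=pd.DataFrame(contrib[:, :-1], columns=names),
            base_values=contrib[:, -1].astype(float),
        )
    bg = design_matrix(background if background is not None else rows, model.feature_names)
    if len(bg) > max_background:
        rng = np.random.default_rng(seed)
        bg = bg.iloc[np.sort(rng.choice(len(bg), size=max_background, replace=False))]
    return _interventional_shap(model, X.to_numpy(float), bg.to_numpy(float), names)


def _interventional_shap(
    model: FittedModel, X: np.ndarray, bg: np.ndarray, names: list[str]
) -> ShapSummary:
    """Exact interventional Shapley values by coalition enumeration."""
    n, k = X.shape
    m = len(bg)
    # v[S] per row: mean over background of f(x_S, bg_complement)
    subset_values: dict[frozenset, np.ndarray] = {}
    for r in range(k + 1):
        for S in itertools.combinations(range(k), r):
            Z = np.repeat(bg[None, :, :], n, axis=0)  # (n, m, k)
            for j in S:
                Z[:, :, j] = X[:, j][:, None]
            Zdf = pd.DataFrame(Z.reshape(n * m, k), columns=names)
            preds = np.asarray(model.estimator.predict(Zdf), dtype=float).reshape(n, m)
            subset_values[frozenset(S)] = preds.mean(axis=1)
    fact = [math.factorial(i) for i in range(k + 1)]
    phi = np.zeros((n, k))
    for i in range(k):
        others = [j for j in range(k) if j != i]
        for r in range(k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for S in itertools.combinations(others, r):
                fs = frozenset(S)
                phi[:, i] += w * (subset_values[fs | {i}] - subset_values[fs])
    base = subset_values[frozenset()]
    return ShapSummary(values=pd.DataFrame(phi, columns=names), base_values=base)


# ----------------------------------------------------------------- report


@dataclass
class EvalReport:
    """Everything the evaluation battery computes for one fitted model."""

    algorithm: str
    pearson_r: float
    mae_deg: float
    residuals: np.ndarray
    per_angle_summary: pd.DataFrame
    feature_correlations: pd.DataFrame
    importance: pd.Series | None = None
    shap: ShapSummary | None = None
    n_test: int = 0

    def to_json_dict(self) -> dict:
        out = {
            "algorithm": self.algorithm,
            "pearson_r": self.pearson_r,
            "mae_deg": self.mae_deg,
            "n_test": self.n_test,
            "per_angle_summary": {
                str(angle): {
                    "mean_deg": float(row["mean_deg"]),
                    "sd_deg": float(row["sd_deg"]),
                    "n": int(row["n"]),
                }
                for angle, row in self.per_angle_summary.iterrows()
            },
        }
        if self.importance is not None:
            out["importance"] = {k: float(v) for k, v in self.importance.items()}
        if self.shap is not None:
            out["mean_abs_shap"] = {
                k: float(v) for k, v in self.shap.mean_abs().items()
            }
        return out


def build_report(
    model: FittedModel,
    test: pd.DataFrame,
    nominal: np.ndarray | None = None,
    with_attributions: bool | None = None,
    shap_rows: int | None = 2048,
    seed: int = 0,
) -> EvalReport:
    """Run the full evaluation battery for one model on held-out rows.

    ``nominal`` gives each row's design (clip target) angle for the
    per-angle residual table; when omitted, each row's true angle rounded to
    the nearest design step of 10° is used. Attribution stages run for tree
    ensembles unless ``with_attributions=False``; SHAP is computed on at
    most ``shap_rows`` rows (None = all) to keep large reports fast.
    """
    true = test["true_angle_deg"].to_numpy(dtype=float)
    pred = model.predict(test)
    if nominal is None:
        nominal = np.round(true / 10.0) * 10.0
    if with_attributions is None:
        with_attributions = is_tree_ensemble(model)
    importance = shap = None
    if with_attributions:
        importance = tree_feature_importance(model)
        rows = test
        if shap_rows is not None and len(test) > shap_rows:
            rng = np.random.default_rng(seed)
            rows = test.iloc[np.sort(rng.choice(len(test), shap_rows, replace=False))]
        shap = shap_attributions(model, rows, seed=seed)
    return EvalReport(
        algorithm=model.spec.algorithm,
        pearson_r=pearson(pred, true),
        mae_deg=mae(true, pred),
        residuals=true - pred,
        per_angle_summary=residual_by_angle(true, pred, nominal),
        feature_correlations=feature_correlation_matrix(test),
        importance=importance,
        shap=shap,
        n_test=len(test),
    )


def save_report(report: EvalReport, out_dir: str | Path, plots: bool = True) -> Path:
    """Write report.json, CSV tables and (optionally) diagnostic plots."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report.to_json_dict(), fh, indent=2)
    report.per_angle_summary.to_csv(out_dir / "residuals_by_angle.csv")
    report.feature_correlations.to_csv(out_dir / "correlations.csv")
    if report.importance is not None:
        report.importance.to_csv(out_dir / "importance.csv", header=True)
    if report.shap is not None:
        summary = pd.DataFrame(
            {"mean_abs_shap": report.shap.mean_abs()}
        )
        summary.to_csv(out_dir / "shap_summary.csv")
    if plots:
        _save_plots(report, out_dir)
    return out_dir


def _save_plots(report: EvalReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # residual plot: residual (actual - predicted) vs nominal angle
    fig, ax = plt.subplots(figsize=(6, 4))
    s = report.per_angle_summary
    ax.errorbar(s.index, s["mean_deg"], yerr=s["sd_deg"], fmt="o", capsize=3)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xlabel("design angle (deg)")
    ax.set_ylabel("residual, actual − predicted (deg)")
    ax.set_title(f"{report.algorithm}: residuals by angle")
    fig.tight_layout()
    fig.savefig(out_dir / "residuals_by_angle.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    m = report.feature_correlations
    im = ax.imshow(m.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(m)), m.columns, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(m)), m.columns, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_title("feature / angle correlation")
    fig.tight_layout()
    fig.savefig(out_dir / "correlation_heatmap.png", dpi=120)
    plt.close(fig)

    if report.importance is not None:
        fig, ax = plt.subplots(figsize=(6, 3.5))
        imp = report.importance.sort_values()
        ax.barh(imp.index, imp.to_numpy())
        ax.set_xlabel("importance (per-tree gain share)")
        fig.tight_layout()
        fig.savefig(out_dir / "importance.png", dpi=120)
        plt.close(fig)

    if report.shap is not None:
        fig, ax = plt.subplots(figsize=(6, 4))
        order = report.shap.mean_abs().sort_values().index
        rng = np.random.default_rng(0)
        for i, name in enumerate(order):
            v = report.shap.values[name].to_numpy()
            ax.scatter(v, i + rng.uniform(-0.25, 0.25, len(v)), s=4, alpha=0.4)
        ax.set_yticks(range(len(order)), order, fontsize=7)
        ax.axvline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("SHAP value (deg)")
        fig.tight_layout()
        fig.savefig(out_dir / "shap_beeswarm.png", dpi=120)
        plt.close(fig)
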