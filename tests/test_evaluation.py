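"""Metrics against brute-force oracles; importance and SHAP contracts."""

import math

import numpy as np
import pandas as pd
import pytest

from rotometry import (
    ModelSpec,
    SchemaError,
    UnsupportedModelError,
    build_report,
    feature_correlation_matrix,
    fit,
    mae,
    pearson,
    residual_by_angle,
    save_report,
    shap_attributions,
    tree_feature_importance,
)
from rotometry.features import FEATURE_NAMES


def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


class TestMetricOracles:
    def test_pearson_textbook_cases(self):
        x = [1.0, 2.0, 3.0]
        assert pearson(x, x) == 1.0
        assert pearson(x, [-v for v in x]) == -1.0
        assert pearson(x, [2.0, 2.0, 5.0]) == pytest.approx(math.sqrt(3) / 2, abs=1e-12)

    def test_mae_textbook_cases(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([1.0, 2.0, 3.0], [2.0, 2.0, 5.0]) == pytest.approx(1.0)
        assert mae([-50.0, 50.0], [-44.0, 58.0]) == pytest.approx(7.0)

    def test_metrics_match_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = rng.integers(2, 200)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-12)
            brute_mae = sum(abs(a - b) for a, b in zip(x, y)) / n
            assert mae(x, y) == pytest.approx(brute_mae, abs=1e-12)

    def test_zero_variance_correlation_rejected(self):
        with pytest.raises(SchemaError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(SchemaError):
            mae([1.0, 2.0], [1.0])


class TestResidualByAngle:
    def test_perfect_predictions_all_zero(self):
        nominal = np.repeat([-10.0, 10.0], 5)
        v = np.arange(10.0)
        out = residual_by_angle(v, v, nominal)
        assert (out["mean_deg"] == 0).all() and (out["sd_deg"] == 0).all()

    def test_two_point_group_sample_sd(self):
        out = residual_by_angle([1.0, -1.0], [0.0, 0.0], [30.0, 30.0])
        assert out.loc[30.0, "mean_deg"] == pytest.approx(0.0)
        assert out.loc[30.0, "sd_deg"] == pytest.approx(math.sqrt(2), abs=1e-12)

    def test_counts_conserved_and_index_ascending(self):
        rng = np.random.default_rng(0)
        nominal = rng.choice([-50.0, -20.0, 0.0, 30.0], size=200)
        true = rng.normal(size=200)
        pred = rng.normal(size=200)
        out = residual_by_angle(true, pred, nominal)
        assert out["n"].sum() == 200
        assert list(out.index) == sorted(out.index)

    def test_singleton_group_flagged_with_zero_sd(self):
        out = residual_by_angle([1.0, 2.0, 3.0], [0.0] * 3, [10.0, 10.0, 20.0])
        assert bool(out.loc[20.0, "single"]) is True
        assert out.loc[20.0, "sd_deg"] == 0.0

    def test_weighted_group_means_recover_overall_mean(self):
        rng = np.random.default_rng(5)
        true = rng.normal(size=500)
        pred = rng.normal(size=500)
        nominal = rng.choice([-40.0, 0.0, 40.0], size=500)
        out = residual_by_angle(true, pred, nominal)
        weighted = (out["mean_deg"] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(np.mean(true - pred), abs=1e-12)

    def test_brute_force_group_statistics(self):
        rng = np.random.default_rng(8)
        true = rng.normal(size=60)
        pred = rng.normal(size=60)
        nominal = rng.choice([-10.0, 10.0], size=60)
        out = residual_by_angle(true, pred, nominal)
        for angle in (-10.0, 10.0):
            res = [(t - p) for t, p, a in zip(true, pred, nominal) if a == angle]
            m = sum(res) / len(res)
            sd = math.sqrt(sum((r - m) ** 2 for r in res) / (len(res) - 1))
            assert out.loc[angle, "mean_deg"] == pytest.approx(m, abs=1e-12)
            assert out.loc[angle, "sd_deg"] == pytest.approx(sd, abs=1e-12)


class TestCorrelationMatrix:
    def test_symmetric_with_unit_diagonal(self, tiny_features):
        m = feature_correlation_matrix(tiny_features)
        assert m.shape == (8, 8)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert np.all(np.diag(m.to_numpy()) == 1.0)

    def test_signed_area_feature_dominates_trunk_angle(self):
        """The parallelogram-area feature correlates with the angle far more
        than the trunk angle does (which only varies through jitter)."""
        from rotometry import SimulationPlan, extract_feature_table, simulate

        feats = extract_feature_table(
            simulate(SimulationPlan(n_subjects=2, frames_per_clip=10, seed=6))
        )
        m = feature_correlation_matrix(feats)
        col = m["true_angle_deg"]
        assert abs(col["norm_elbow_size"]) > abs(col["trunk_angle"])

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame(
            np.random.default_rng(0).normal(size=(20, 8)),
            columns=list(FEATURE_NAMES) + ["true_angle_deg"],
        )
        df["trunk_angle"] = 90.0
        m = feature_correlation_matrix(df)
        off_diag = m["trunk_angle"].drop("trunk_angle")
        assert off_diag.isna().all()
        assert m.loc["trunk_angle", "trunk_angle"] == 1.0


class TestImportance:
    def test_sums_to_one_for_both_ensembles(self, default_split, gbt_model):
        imp = tree_feature_importance(gbt_model)
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp >= 0).all()
        rf = fit(ModelSpec(algorithm="random_forest", seed=0), default_split.train.head(500))
        imp_rf = tree_feature_importance(rf)
        assert imp_rf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (imp_rf >= 0).all()

    def test_single_feature_tree_gets_all_importance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(0.0, index=range(200), columns=list(FEATURE_NAMES))
        df["norm_elbow_size"] = rng.uniform(-1, 1, 200)
        df["true_angle_deg"] = 50 * df["norm_elbow_size"]
        model = fit(
            ModelSpec(algorithm="random_forest", seed=0,
                      hyperparameters={"n_estimators": 3, "max_depth": 2}),
            df,
        )
        imp = tree_feature_importance(model)
        assert imp["norm_elbow_size"] == pytest.approx(1.0)

    def test_non_tree_model_rejected(self, ols_model):
        with pytest.raises(UnsupportedModelError):
            tree_feature_importance(ols_model)


class TestShap:
    def test_local_accuracy_for_boosted_model(self, gbt_model, default_split):
        rows = default_split.test.head(200)
        sh = shap_attributions(gbt_model, rows)
        gap = sh.local_accuracy_gap(gbt_model.predict(rows))
        assert np.abs(gap).max() < 1e-6

    def test_local_accuracy_for_random_forest_exact_enumeration(self, default_split):
        rf = fit(
            ModelSpec(algorithm="random_forest", seed=0,
                      hyperparameters={"n_estimators": 5}),
            default_split.train.head(300),
        )
        rows = default_split.test.head(5)
        sh = shap_attributions(rf, rows, background=default_split.train.head(40))
        gap = sh.local_accuracy_gap(rf.predict(rows))
        assert np.abs(gap).max() < 1e-9

    def test_constant_model_has_zero_attributions(self):
        df = pd.DataFrame(
            np.random.default_rng(3).normal(size=(50, 7)), columns=list(FEATURE_NAMES)
        )
        df["true_angle_deg"] = 7.5
        with pytest.warns(RuntimeWarning, match="constant"):
            model = fit(ModelSpec(algorithm="random_forest", seed=0), df)
        sh = shap_attributions(model, df.head(4))
        assert np.abs(sh.values.to_numpy()).max() < 1e-9
        assert sh.base_values == pytest.approx([7.5] * 4, abs=1e-9)

    def test_extreme_signed_area_gets_positive_attribution(self, gbt_model, default_split):
        test = default_split.test
        idx = test["norm_elbow_size"].idxmax()
        row = test.loc[[idx]]
        sh = shap_attributions(gbt_model, row)
        assert sh.values["norm_elbow_size"].iloc[0] > 0

    def test_non_tree_model_rejected(self, ols_model, default_split):
        with pytest.raises(UnsupportedModelError):
            shap_attributions(ols_model, default_split.test.head(2))


class TestReport:
    def test_report_assembles_and_serializes(self, gbt_model, default_split, tmp_path):
        report = build_report(
            gbt_model, default_split.test.head(400), shap_rows=100, seed=0
        )
        assert -1 <= report.pearson_r <= 1
        assert report.mae_deg >= 0
        assert report.importance is not None and report.shap is not None
        out = save_report(report, tmp_path / "rep", plots=False)
        for name in ("report.json", "residuals_by_angle.csv", "correlations.csv",
                     "importance.csv", "shap_summary.csv"):
            assert (out / name).exists(), name
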