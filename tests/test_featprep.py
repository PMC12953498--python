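"""Scaling, Pearson selection, outlier fences and engineered features."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler

from ppglucose import (
    CorrelationSelector,
    FeatureEngineer,
    MinMaxFeatureScaler,
    engineer_features,
    minmax_scale,
    pearson_r,
    remove_outliers,
    select_features,
)
from ppglucose.featprep import FeaturePrepError, ScalingParams


def table_of(**cols):
    return pd.DataFrame(cols)


class TestMinMaxScale:
    def test_unit_range(self):
        out, _ = minmax_scale(table_of(f=[0.0, 5.0, 10.0], glucose_mgdl=[90, 100, 110]))
        np.testing.assert_allclose(out["f"], [0.0, 0.5, 1.0])

    def test_symmetric_range_by_hand(self):
        out, _ = minmax_scale(
            table_of(f=[0.0, 5.0, 10.0], glucose_mgdl=[90, 100, 110]),
            feature_range=(-1.0, 1.0),
        )
        np.testing.assert_allclose(out["f"], [-1.0, 0.0, 1.0])

    def test_stored_params_are_idempotent(self):
        t = table_of(f=[1.0, 4.0, 9.0], glucose_mgdl=[90, 100, 110])
        out1, params = minmax_scale(t)
        out2, _ = minmax_scale(t, params=params)
        assert out1.equals(out2)

    def test_constant_column_maps_to_minimum_with_warning(self):
        t = table_of(f=[3.0, 3.0, 3.0], glucose_mgdl=[90, 100, 110])
        with pytest.warns(RuntimeWarning):
            out, _ = minmax_scale(t, feature_range=(-1.0, 1.0))
        assert (out["f"] == -1.0).all()

    def test_matches_sklearn(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        t["glucose_mgdl"] = rng.uniform(70, 150, 30)
        out, _ = minmax_scale(t, feature_range=(0.0, 1.0))
        ref = MinMaxScaler().fit_transform(t[list("abcd")])
        np.testing.assert_allclose(out[list("abcd")].to_numpy(), ref, rtol=1e-12)

    def test_metadata_passthrough(self):
        t = table_of(f=[0.0, 1.0, 3.0], glucose_mgdl=[90, 100, 110], state=["fasting"] * 3, subject_id=["a", "b", "c"])
        out, _ = minmax_scale(t)
        assert (out["glucose_mgdl"] == t["glucose_mgdl"]).all()
        assert (out["state"] == t["state"]).all()

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=20, unique=True))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_order_preserving(self, values):
        t = table_of(f=values, glucose_mgdl=list(np.linspace(70, 150, len(values))))
        out, _ = minmax_scale(t)
        order = np.argsort(t["f"].to_numpy())
        assert np.all(np.diff(out["f"].to_numpy()[order]) >= 0)


def pearson_sum_formula(a, b):
    """Corrected sum-of-products oracle for Pearson's r."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    n = a.size
    num = n * np.sum(a * b) - np.sum(a) * np.sum(b)
    den = np.sqrt((n * np.sum(a**2) - np.sum(a) ** 2) * (n * np.sum(b**2) - np.sum(b) ** 2))
    return num / den


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, 2 * x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_sum_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=rng.integers(3, 50))
            y = rng.normal(size=x.size)
            assert abs(pearson_r(x, y) - pearson_sum_formula(x, y)) < 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(FeaturePrepError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(FeaturePrepError):
            pearson_r(np.arange(4.0), np.arange(5.0))

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_symmetry_and_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = pearson_r(x, y)
        assert pearson_r(y, x) == pytest.approx(r, rel=1e-9)
        assert pearson_r(scale * x + shift, y) == pytest.approx(r, rel=1e-6, abs=1e-9)


class TestSelectFeatures:
    def test_exact_copy_of_target_always_selected(self):
        g = np.linspace(70, 150, 40)
        t = table_of(copy=g, noise=np.sin(np.arange(40.0) * 12.9898), glucose_mgdl=g)
        res = select_features(t, threshold=0.3)
        assert res.selected[0] == "copy"
        assert res.r_by_feature["copy"] == pytest.approx(1.0)

    def test_pure_noise_features_excluded(self):
        rng = np.random.default_rng(0)
        g = rng.uniform(70, 150, 160)
        cols = {f"n{i}": rng.normal(size=160) for i in range(50)}
        t = table_of(planted=g + rng.normal(0, 5, 160), **cols, glucose_mgdl=g)
        res = select_features(t, threshold=0.3)
        assert res.selected == ["planted"]

    def test_zero_threshold_selects_all_nonconstant(self):
        rng = np.random.default_rng(1)
        t = table_of(a=rng.normal(size=20), b=rng.normal(size=20), glucose_mgdl=rng.uniform(70, 150, 20))
        res = select_features(t, threshold=0.0)
        assert set(res.selected) == {"a", "b"}

    def test_no_feature_passes_raises_with_advice(self):
        rng = np.random.default_rng(2)
        t = table_of(a=rng.normal(size=200), glucose_mgdl=rng.uniform(70, 150, 200))
        with pytest.raises(FeaturePrepError, match="threshold"):
            select_features(t, threshold=0.9)

    def test_report_contains_every_feature(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(70, 150, 30)
        t = table_of(a=g * 2, b=rng.normal(size=30), glucose_mgdl=g)
        rep = select_features(t, threshold=0.3).report()
        assert set(rep["feature"]) == {"a", "b"}
        assert rep.loc[rep.feature == "a", "selected"].item()

    def test_selection_invariant_under_scaling(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(70, 150, 60)
        t = table_of(a=g + rng.normal(0, 10, 60), b=rng.normal(size=60), glucose_mgdl=g)
        scaled, _ = minmax_scale(t)
        sel_raw = select_features(t, threshold=0.3).selected
        sel_scaled = select_features(scaled, threshold=0.3).selected
        assert sel_raw == sel_scaled


class TestRemoveOutliers:
    def test_well_behaved_table_is_identity(self):
        rng = np.random.default_rng(0)
        t = table_of(a=rng.uniform(0, 1, 40), glucose_mgdl=rng.uniform(70, 150, 40))
        out, log = remove_outliers(t, feature_columns=["a"])
        assert out.equals(t) and log.empty

    def test_out_of_range_glucose_removed(self):
        t = table_of(a=np.linspace(0, 1, 5), glucose_mgdl=[90.0, 100.0, 200.0, 110.0, 120.0])
        out, log = remove_outliers(t, feature_columns=["a"])
        assert len(out) == 4 and 200.0 not in out["glucose_mgdl"].to_numpy()
        assert log.iloc[0]["column"] == "glucose_mgdl"

    def test_iqr_fence_removes_planted_extreme(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 30)
        q1, q3 = np.percentile(a, [25, 75])
        a[7] = q3 + 10 * (q3 - q1)
        t = table_of(a=a, glucose_mgdl=rng.uniform(70, 150, 30))
        out, log = remove_outliers(t, feature_columns=["a"])
        assert len(out) == 29 and 7 not in out.index
        assert (log["column"] == "a").all()

    def test_all_rows_removed_raises(self):
        t = table_of(a=[0.0, 1.0], glucose_mgdl=[200.0, 300.0])
        with pytest.raises(FeaturePrepError):
            remove_outliers(t, feature_columns=["a"])


class TestEngineerFeatures:
    BASE = {
        "ppg_max": 3.0, "vpg_max": 2.0, "apg_max": 1.0,
        "ppg_mean": 0.3, "vpg_mean": 0.2, "apg_mean": 0.1,
        "ppg_sd": 0.9, "vpg_sd": 0.6, "apg_sd": 0.3,
        "ppg_var": 0.81, "vpg_var": 0.36, "apg_var": 0.09,
        "s_peak": 1.0, "d_peak": 0.4,
    }

    def test_hand_arithmetic(self):
        e = engineer_features(self.BASE)
        assert e["maximum"] == pytest.approx(2.0)
        assert e["mean"] == pytest.approx(0.2)
        assert e["peak_ratios"] == pytest.approx(2.5)
        assert e["sd"] == pytest.approx(0.6)
        assert e["var"] == pytest.approx(0.42)
        assert e["sdmean"] == e["sd"] - e["mean"]  # exact identity

    def test_equal_peaks_give_unit_ratio(self):
        v = dict(self.BASE, s_peak=0.7, d_peak=0.7)
        assert engineer_features(v)["peak_ratios"] == pytest.approx(1.0)

    def test_purity(self):
        assert engineer_features(dict(self.BASE)) == engineer_features(dict(self.BASE))

    def test_zero_diastolic_peak_rejected(self):
        with pytest.raises(FeaturePrepError):
            engineer_features(dict(self.BASE, d_peak=0.0))

    def test_dataframe_form_matches_rowwise(self):
        t = pd.DataFrame([self.BASE, dict(self.BASE, s_peak=2.0)])
        out = FeatureEngineer().fit(t).transform(t)
        assert list(out.columns) == ["maximum", "mean", "peak_ratios", "sd", "var", "sdmean"]
        assert out.iloc[0]["peak_ratios"] == pytest.approx(2.5)
        assert out.iloc[1]["peak_ratios"] == pytest.approx(5.0)


class TestEstimators:
    def test_scaler_learns_on_training_rows_only(self, feature_table):
        X = feature_table.drop(columns=["glucose_mgdl", "state", "subject_id"])
        train, test = X.iloc[:12], X.iloc[12:]
        scaler = MinMaxFeatureScaler().fit(train)
        out_train = scaler.transform(train)
        num = out_train.select_dtypes(float)
        assert num.min().min() >= 0.0 - 1e-12 and num.max().max() <= 1.0 + 1e-12
        # test rows may fall outside [0,1]: parameters came from train only
        assert scaler.transform(test).shape == test.shape

    def test_correlation_selector_in_pipeline(self, feature_table):
        X = feature_table.drop(columns=["glucose_mgdl", "state", "subject_id"])
        y = feature_table["glucose_mgdl"]
        pipe = Pipeline([("scale", MinMaxFeatureScaler()), ("select", CorrelationSelector(0.3))])
        out = pipe.fit_transform(X, y)
        selected = pipe.named_steps["select"].result_.selected
        assert out.shape[1] == len(selected) > 0

    def test_selector_get_support(self, feature_table):
        X = feature_table.drop(columns=["glucose_mgdl", "state", "subject_id"])
        y = feature_table["glucose_mgdl"]
        sel = CorrelationSelector(0.3).fit(X, y)
        assert sel.get_support().sum() == len(sel.result_.selected)
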