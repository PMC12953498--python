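"""Feature scaling, correlation-based selection, outlier removal, engineering.

Min-max scaling maps each feature from its observed [min, max] to a
target range (default [0, 1]).  Feature selection keeps features whose
absolute Pearson correlation with the reference glucose meets a
threshold (default |r| >= 0.3) and reports the full correlation map.
Outlier removal applies the stated glucose inclusion range
(65-160 mg/dL) plus deterministic 1.5 x IQR fences on the selected
feature columns.  Six engineered features condense the shortlist:
per-signal-family averages of Max, Mean, SD and Var, the
systolic-to-diastolic peak ratio, and the SD-minus-Mean difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_is_fitted

from .features import METADATA_COLUMNS

ENGINEERED_COLUMNS = ("maximum", "mean", "peak_ratios", "sd", "var", "sdmean")


class FeaturePrepError(ValueError):
    pass


@dataclass
class ScalingParams:
    """Fitted per-feature min/max plus the target range."""

    data_min: dict[str, float]
    data_max: dict[str, float]
    new_min: float = 0.0
    new_max: float = 1.0


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def minmax_scale(
    table: pd.DataFrame,
    params: ScalingParams | None = None,
    feature_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[pd.DataFrame, ScalingParams]:
    """Scale feature columns to ``feature_range``; metadata passes through.

    With ``params`` given, applies the stored mapping (idempotent for the
    fitting data); otherwise fits min/max per column.  Constant columns
    map to the range minimum with a warning.
    """
    new_min, new_max = feature_range if params is None else (params.new_min, params.new_max)
    if not new_max > new_min:
        raise FeaturePrepError("feature range must satisfy new_max > new_min")
    cols = _feature_columns(table)
    out = table.copy()
    if params is None:
        params = ScalingParams(
            data_min={c: float(np.nanmin(table[c])) for c in cols},
            data_max={c: float(np.nanmax(table[c])) for c in cols},
            new_min=new_min,
            new_max=new_max,
        )
    for c in cols:
        lo, hi = params.data_min[c], params.data_max[c]
        if hi == lo:
            warnings.warn(f"constant feature {c!r}: mapped to range minimum", RuntimeWarning, stacklevel=2)
            out[c] = new_min
        else:
            out[c] = (table[c] - lo) / (hi - lo) * (new_max - new_min) + new_min
    return out, params


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise FeaturePrepError("pearson_r needs equal-length inputs")
    if x.size < 3:
        raise FeaturePrepError("pearson_r needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise FeaturePrepError("correlation undefined for a constant input")
    return float(sstats.pearsonr(x, y).statistic)


@dataclass
class SelectionResult:
    """Correlation map and the shortlist it induces."""

    r_by_feature: dict[str, float]
    threshold: float
    selected: list[str] = field(default_factory=list)

    def report(self) -> pd.DataFrame:
        """Heat-map content: ``feature, r_with_glucose, selected``."""
        return pd.DataFrame(
            {
                "feature": list(self.r_by_feature),
                "r_with_glucose": list(self.r_by_feature.values()),
                "selected": [f in self.selected for f in self.r_by_feature],
            }
        )


def select_features(
    table: pd.DataFrame,
    threshold: float = 0.3,
    target: str = "glucose_mgdl",
    allow_empty: bool = False,
) -> SelectionResult:
    """Shortlist features with |r(feature, glucose)| >= threshold.

    Correlations use pairwise-complete rows (NaNs from absent c/d waves
    are dropped per feature).  Constant or all-NaN features get r = NaN
    and are never selected.
    """
    if target not in table.columns:
        raise FeaturePrepError(f"target column {target!r} missing")
    r_map: dict[str, float] = {}
    for c in _feature_columns(table):
        if c == target:
            continue
        pair = table[[c, target]].dropna()
        try:
            r_map[c] = pearson_r(pair[c].to_numpy(), pair[target].to_numpy())
        except FeaturePrepError:
            r_map[c] = float("nan")
    selected = [c for c, r in r_map.items() if np.isfinite(r) and abs(r) >= threshold]
    selected.sort(key=lambda c: -abs(r_map[c]))
    if not selected and not allow_empty:
        raise FeaturePrepError(
            f"no feature reaches |r| >= {threshold}; lower the selection threshold"
        )
    return SelectionResult(r_by_feature=r_map, threshold=threshold, selected=selected)


def remove_outliers(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    glucose_range: tuple[float, float] = (65.0, 160.0),
    iqr_factor: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows with out-of-range glucose or fenced feature values.

    Rows with reference glucose outside ``glucose_range`` are removed
    (study inclusion rule); rows where any of ``feature_columns`` falls
    beyond ``iqr_factor`` x IQR fences are removed as a deterministic
    surrogate for scatter-plot screening.  Returns the filtered table and
    a removal log (row index, triggering column, value).
    """
    log_rows = []
    keep = np.ones(len(table), dtype=bool)
    g = table["glucose_mgdl"].to_numpy(dtype=float)
    for i, (idx, val) in enumerate(zip(table.index, g)):
        if not glucose_range[0] <= val <= glucose_range[1]:
            keep[i] = False
            log_rows.append({"row": idx, "column": "glucose_mgdl", "value": val})
    cols = feature_columns if feature_columns is not None else _feature_columns(table)
    for c in cols:
        vals = table[c].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size < 4:
            continue
        q1, q3 = np.percentile(finite, [25, 75])
        lo, hi = q1 - iqr_factor * (q3 - q1), q3 + iqr_factor * (q3 - q1)
        for i, (idx, val) in enumerate(zip(table.index, vals)):
            if keep[i] and np.isfinite(val) and not lo <= val <= hi:
                keep[i] = False
                log_rows.append({"row": idx, "column": c, "value": val})
    filtered = table.loc[keep]
    if filtered.empty:
        raise FeaturePrepError("outlier removal dropped every row")
    return filtered, pd.DataFrame(log_rows, columns=["row", "column", "value"])


def engineer_features(row_or_table) -> pd.DataFrame | dict[str, float]:
    """Build the six engineered features from the 35-feature catalogue.

    maximum = (Max_PPG + Max_VPG + Max_APG)/3, likewise mean, sd, var;
    peak_ratios = S_Peak / D_Peak; sdmean = sd - mean.
    Accepts a single feature mapping (returns a dict) or a table
    (returns a DataFrame with the six columns).
    """
    if isinstance(row_or_table, pd.DataFrame):
        out = pd.DataFrame(index=row_or_table.index)
        t = row_or_table
        if (t["d_peak"] == 0).any():
            raise FeaturePrepError("d_peak = 0: peak ratio undefined")
        out["maximum"] = (t["ppg_max"] + t["vpg_max"] + t["apg_max"]) / 3
        out["mean"] = (t["ppg_mean"] + t["vpg_mean"] + t["apg_mean"]) / 3
        out["peak_ratios"] = t["s_peak"] / t["d_peak"]
        out["sd"] = (t["ppg_sd"] + t["vpg_sd"] + t["apg_sd"]) / 3
        out["var"] = (t["ppg_var"] + t["vpg_var"] + t["apg_var"]) / 3
        out["sdmean"] = out["sd"] - out["mean"]
        return out
    v = row_or_table
    if v["d_peak"] == 0:
        raise FeaturePrepError("d_peak = 0: peak ratio undefined")
    mean = (v["ppg_mean"] + v["vpg_mean"] + v["apg_mean"]) / 3
    sd = (v["ppg_sd"] + v["vpg_sd"] + v["apg_sd"]) / 3
    return {
        "maximum": (v["ppg_max"] + v["vpg_max"] + v["apg_max"]) / 3,
        "mean": mean,
        "peak_ratios": v["s_peak"] / v["d_peak"],
        "sd": sd,
        "var": (v["ppg_var"] + v["vpg_var"] + v["apg_var"]) / 3,
        "sdmean": sd - mean,
    }


class MinMaxFeatureScaler(BaseEstimator, TransformerMixin):
    """Min-max scaling estimator over DataFrame feature columns.

    Wraps :class:`sklearn.preprocessing.MinMaxScaler`; when fitted inside
    a model pipeline the min/max are learned on training rows only.
    """

    def __init__(self, feature_range: tuple[float, float] = (0.0, 1.0)):
        self.feature_range = feature_range

    def fit(self, X: pd.DataFrame, y=None):
        self.columns_ = [c for c in X.columns if c not in METADATA_COLUMNS]
        self.scaler_ = MinMaxScaler(feature_range=self.feature_range, clip=False)
        self.scaler_.fit(X[self.columns_])
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scaler_")
        out = X.copy()
        out[self.columns_] = self.scaler_.transform(X[self.columns_])
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "scaler_")
        return np.asarray(self.columns_, dtype=object)


class CorrelationSelector(SelectorMixin, BaseEstimator):
    """Select features by |Pearson r| with the target (default 0.3)."""

    def __init__(self, threshold: float = 0.3):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        work = X.copy()
        work["glucose_mgdl"] = np.asarray(y, dtype=float)
        result = select_features(work, threshold=self.threshold)
        self.result_ = result
        self.support_ = np.asarray([c in result.selected for c in X.columns])
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        return X.loc[:, self.support_]


class FeatureEngineer(BaseEstimator, TransformerMixin):
    """Stateless transformer producing the six engineered features."""

    def fit(self, X, y=None):
        self.n_features_in_ = pd.DataFrame(X).shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return engineer_features(pd.DataFrame(X))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(ENGINEERED_COLUMNS, dtype=object)
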