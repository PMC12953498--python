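"""Regression model zoo, 50/50 evaluation, and agreement analysis.

Trains the candidate regressors (random forest, support-vector machine,
k-nearest neighbours, gradient-boosted trees, decision tree, linear) on
a feature table with a 50/50 train/test split, and reproduces the full
evaluation surface: R2/MAE/RMSE/MSE, the difference histogram summary,
Bland-Altman limits of agreement, and glucose-range-stratified bias.

The difference convention is everywhere predicted - actual.  The default
split is record-level (mirroring an 80/80 record split of a paired
cohort); subject-level grouping is available and avoids placing one
subject's fasting and postprandial records on opposite sides, which the
record-level split cannot guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GroupShuffleSplit, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .features import METADATA_COLUMNS

ALGORITHMS = (
    "random_forest",
    "svm",
    "knn",
    "gradient_boosted_trees",
    "decision_tree",
    "linear",
)

#: Published random-forest setting used for the headline evaluation.
RANDOM_FOREST_DEFAULTS = dict(
    n_estimators=100,
    max_depth=10,
    min_samples_split=2,
    min_samples_leaf=1,
    max_features="sqrt",
    bootstrap=True,
    random_state=42,
)


class ModelError(ValueError):
    pass


@dataclass
class ModelSpec:
    """One candidate regressor: algorithm name + hyperparameter overrides."""

    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ModelError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class SplitSpec:
    """Train/test partition: fraction, seed and grouping level."""

    train_fraction: float = 0.5
    seed: int = 42
    grouping: str = "record"

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ModelError("train_fraction must lie strictly between 0 and 1")
        if self.grouping not in ("record", "subject"):
            raise ModelError("grouping must be 'record' or 'subject'")


@dataclass
class PredictionSet:
    """Paired actual/predicted glucose values on the test set."""

    actual: np.ndarray
    predicted: np.ndarray
    subject_id: np.ndarray | None = None
    state: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        if self.actual.size != self.predicted.size:
            raise ModelError("actual and predicted must have equal length")

    @property
    def differences(self) -> np.ndarray:
        return self.predicted - self.actual

    @property
    def n(self) -> int:
        return self.actual.size

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"actual": self.actual, "predicted": self.predicted})
        if self.subject_id is not None:
            out.insert(0, "subject_id", self.subject_id)
        if self.state is not None:
            out.insert(1, "state", self.state)
        return out


@dataclass
class MetricsReport:
    mse: float
    rmse: float
    mae: float
    r2: float


@dataclass
class RangeBiasRow:
    """Per-glucose-range comparison of predicted vs actual."""

    range_label: str
    n: int
    mean_predicted: float | None
    mean_actual: float | None
    mean_difference: float | None
    sd_predicted: float | None
    sd_actual: float | None
    sd_differences: float | None


@dataclass
class BlandAltmanSummary:
    bias: float
    sd_differences: float
    loa_lower: float
    loa_upper: float
    within_10_fraction: float


def make_estimator(spec: ModelSpec):
    """Instantiate the sklearn/xgboost estimator for a spec, seeded."""
    hp = dict(spec.hyperparameters)
    if spec.algorithm == "random_forest":
        params = {**RANDOM_FOREST_DEFAULTS, **hp}
        return RandomForestRegressor(**params)
    if spec.algorithm == "svm":
        return SVR(**hp)
    if spec.algorithm == "knn":
        return KNeighborsRegressor(**hp)
    if spec.algorithm == "gradient_boosted_trees":
        from xgboost import XGBRegressor

        hp.setdefault("n_estimators", 100)
        hp.setdefault("random_state", spec.seed)
        return XGBRegressor(**hp)
    if spec.algorithm == "decision_tree":
        hp.setdefault("random_state", spec.seed)
        return DecisionTreeRegressor(**hp)
    return LinearRegression(**hp)


def split_data(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split at the record or subject level."""
    spec = spec or SplitSpec()
    if len(table) < 4:
        raise ModelError("need at least 4 rows to split")
    if spec.grouping == "record":
        train, test = train_test_split(
            table, train_size=spec.train_fraction, random_state=spec.seed, shuffle=True
        )
        return train, test
    if "subject_id" not in table.columns:
        raise ModelError("subject grouping requires a subject_id column")
    gss = GroupShuffleSplit(n_splits=1, train_size=spec.train_fraction, random_state=spec.seed)
    idx_train, idx_test = next(gss.split(table, groups=table["subject_id"]))
    return table.iloc[idx_train], table.iloc[idx_test]


def _xy(table: pd.DataFrame, feature_columns: list[str] | None = None):
    cols = feature_columns or [c for c in table.columns if c not in METADATA_COLUMNS]
    X = table[cols]
    bad = [c for c in cols if not np.all(np.isfinite(X[c].to_numpy(dtype=float)))]
    if bad:
        raise ModelError(f"non-finite values in feature columns: {bad}")
    y = table["glucose_mgdl"].to_numpy(dtype=float)
    return X, y, cols


def fit_model(train: pd.DataFrame, spec: ModelSpec, feature_columns: list[str] | None = None):
    """Fit one regressor on a feature table; returns the fitted estimator."""
    X, y, cols = _xy(train, feature_columns)
    est = make_estimator(spec)
    est.fit(X.to_numpy(dtype=float), y)
    est.feature_columns_ = cols
    return est


def predict_set(est, test: pd.DataFrame) -> PredictionSet:
    X = test[est.feature_columns_].to_numpy(dtype=float)
    return PredictionSet(
        actual=test["glucose_mgdl"].to_numpy(dtype=float),
        predicted=np.asarray(est.predict(X), dtype=float),
        subject_id=test["subject_id"].to_numpy() if "subject_id" in test.columns else None,
        state=test["state"].to_numpy() if "state" in test.columns else None,
    )


def evaluate_metrics(pred: PredictionSet) -> MetricsReport:
    """MSE ((mg/dL)^2), RMSE, MAE (mg/dL) and R2."""
    if pred.n < 2:
        raise ModelError("metrics need at least 2 predictions")
    if np.all(pred.actual == pred.actual[0]):
        raise ModelError("R2 undefined for constant actual values")
    mse = float(skm.mean_squared_error(pred.actual, pred.predicted))
    return MetricsReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(skm.mean_absolute_error(pred.actual, pred.predicted)),
        r2=float(skm.r2_score(pred.actual, pred.predicted)),
    )


def bland_altman(pred: PredictionSet, limit_mgdl: float = 10.0) -> BlandAltmanSummary:
    """Mean bias, 95% limits of agreement, and the within-limit fraction.

    Differences are predicted - actual; limits are bias +/- 1.96 x sample
    SD of the differences (0 when n < 2 distinct differences).
    """
    if pred.n < 2:
        raise ModelError("Bland-Altman needs at least 2 pairs")
    d = pred.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanSummary(
        bias=bias,
        sd_differences=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        within_10_fraction=float(np.mean(np.abs(d) <= limit_mgdl)),
    )


def range_bias(
    pred: PredictionSet, boundaries: tuple[float, float] = (90.0, 120.0)
) -> list[RangeBiasRow]:
    """Table of per-glucose-range statistics, partitioned by ACTUAL value.

    Ranges are [<b0), [b0, b1), [>= b1]; empty ranges report n = 0 with
    absent statistics.  SDs are sample (n-1) SDs, NaN-free only for n >= 2.
    """
    b0, b1 = boundaries
    labels = [f"<{b0:g}", f"{b0:g}-{b1:g}", f">={b1:g}"]
    masks = [
        pred.actual < b0,
        (pred.actual >= b0) & (pred.actual < b1),
        pred.actual >= b1,
    ]
    rows = []
    for label, mask in zip(labels, masks):
        n = int(np.sum(mask))
        if n == 0:
            rows.append(RangeBiasRow(label, 0, None, None, None, None, None, None))
            continue
        act, prd = pred.actual[mask], pred.predicted[mask]
        d = prd - act
        sd = lambda v: float(np.std(v, ddof=1)) if v.size >= 2 else None
        rows.append(
            RangeBiasRow(
                range_label=label,
                n=n,
                mean_predicted=float(np.mean(prd)),
                mean_actual=float(np.mean(act)),
                mean_difference=float(np.mean(d)),
                sd_predicted=sd(prd),
                sd_actual=sd(act),
                sd_differences=sd(d),
            )
        )
    return rows


def range_bias_frame(rows: list[RangeBiasRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "glucose_range_mgdl": r.range_label,
                "n": r.n,
                "mean_predicted_mgdl": r.mean_predicted,
                "mean_actual_mgdl": r.mean_actual,
                "mean_difference_mgdl": r.mean_difference,
                "sd_predicted_mgdl": r.sd_predicted,
                "sd_actual_mgdl": r.sd_actual,
                "sd_differences_mgdl": r.sd_differences,
            }
            for r in rows
        ]
    )


def compare_models(
    table: pd.DataFrame,
    specs: list[ModelSpec],
    split: SplitSpec | None = None,
    feature_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Train/evaluate every spec on one identical split; rank by RMSE.

    Per-model failures are recorded (error column) and do not stop the
    comparison.
    """
    if len(specs) < 2:
        raise ModelError("compare_models needs at least 2 specs")
    train, test = split_data(table, split)
    rows = []
    for i, spec in enumerate(specs):
        row: dict = {"rank_key": i, "algorithm": spec.algorithm}
        try:
            est = fit_model(train, spec, feature_columns)
            rep = evaluate_metrics(predict_set(est, test))
            row.update(mse=rep.mse, rmse=rep.rmse, mae=rep.mae, r2=rep.r2, error="")
        except Exception as exc:  # noqa: BLE001 - per-model failure is data
            row.update(mse=np.nan, rmse=np.nan, mae=np.nan, r2=np.nan, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows).drop(columns="rank_key")
    return out.sort_values("rmse", na_position="last", kind="stable").reset_index(drop=True)
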