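"""End-to-end orchestration: config, seeded substreams, artifacts, manifest.

A run is described by a :class:`RunConfig` (1:1 with a YAML file; unknown
keys are rejected) and executes simulate -> preprocess -> feature
extraction -> feature prep -> model training -> evaluation, writing
every intermediate artifact as CSV/JSON under the output directory plus
a run manifest sufficient to re-execute the run bit-identically.

All randomness flows from the single global seed through named per-stage
substreams, so identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import os
import warnings
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd
import yaml
from sklearn.impute import SimpleImputer
from sklearn.pipeline import FeatureUnion, Pipeline

from . import __version__
from .featprep import (
    CorrelationSelector,
    FeatureEngineer,
    MinMaxFeatureScaler,
    remove_outliers,
    select_features,
)
from .features import (
    FEATURE_COLUMNS,
    WaveformFeatureExtractor,
    write_feature_table,
)
from .model import (
    ModelSpec,
    PredictionSet,
    SplitSpec,
    bland_altman,
    evaluate_metrics,
    make_estimator,
    range_bias,
    range_bias_frame,
    split_data,
)
from .preprocess import FilterSpec, band_snr, preprocess_record
from .records import read_cohort, write_cohort
from .synth import MorphologyParams, NoiseConfig, SynthConfig, generate_cohort


class ConfigError(ValueError):
    pass


FEATURE_MODES = ("engineered", "selected", "combined")


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 42
    out_dir: str = "run_out"
    input_dir: str | None = None  # read records instead of simulating
    n_subjects: int = 80
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    filter: dict = field(default_factory=dict)  # FilterSpec overrides
    segmentation: dict = field(default_factory=dict)  # extractor overrides
    selection_threshold: float = 0.3
    feature_range: tuple[float, float] = (0.0, 1.0)
    iqr_factor: float = 1.5
    glucose_range: tuple[float, float] = (65.0, 160.0)
    feature_mode: str = "engineered"
    write_records: bool = True  # per-record CSVs are the bulkiest artifact
    algorithm: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    train_fraction: float = 0.5
    grouping: str = "record"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ConfigError(f"feature_mode must be one of {FEATURE_MODES}")


def load_config(path: str) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("feature_range", "glucose_range"):
        if key in data:
            data[key] = tuple(data[key])
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    ss = np.random.SeedSequence([global_seed, abs(hash_stage(stage))])
    return int(ss.generate_state(1)[0] % (2**31))


def hash_stage(stage: str) -> int:
    # stable across processes (unlike built-in hash on str)
    h = 0
    for ch in stage:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def build_synth_config(cfg: RunConfig) -> SynthConfig:
    overrides = dict(cfg.synth)
    morph = overrides.pop("morphology", None)
    noise = overrides.pop("noise", None)
    known = {f.name for f in fields(SynthConfig)}
    unknown = set(overrides) - known
    if unknown:
        raise ConfigError(f"unknown synth keys {sorted(unknown)}")
    sc = SynthConfig(
        n_subjects=cfg.n_subjects, seed=stage_seed(cfg.seed, "synth"), **overrides
    )
    if morph:
        sc = replace(sc, morphology=MorphologyParams(**morph))
    if noise:
        sc = replace(sc, noise=NoiseConfig(**noise))
    return sc


def build_model_pipeline(cfg: RunConfig) -> Pipeline:
    """Compose the sklearn model pipeline for the configured feature mode."""
    est = make_estimator(
        ModelSpec(
            algorithm=cfg.algorithm,
            hyperparameters=cfg.hyperparameters,
            seed=stage_seed(cfg.seed, "model"),
        )
    )
    if cfg.feature_mode == "engineered":
        steps = [("engineer", FeatureEngineer()), ("model", est)]
    elif cfg.feature_mode == "selected":
        steps = [
            ("impute", SimpleImputer(strategy="median").set_output(transform="pandas")),
            ("scale", MinMaxFeatureScaler(feature_range=cfg.feature_range)),
            ("select", CorrelationSelector(threshold=cfg.selection_threshold)),
            ("model", est),
        ]
    else:
        union = FeatureUnion(
            [
                ("engineered", FeatureEngineer()),
                (
                    "selected",
                    Pipeline(
                        [
                            ("impute", SimpleImputer(strategy="median").set_output(transform="pandas")),
                            ("scale", MinMaxFeatureScaler(feature_range=cfg.feature_range)),
                            ("select", CorrelationSelector(threshold=cfg.selection_threshold)),
                        ]
                    ),
                ),
            ]
        )
        steps = [("features", union), ("model", est)]
    return Pipeline(steps)


def _write_json_atomic(obj: dict, path: str) -> None:
    tmp = path + ".tmp"
    with open(tmp, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full chain and return the run manifest (also written)."""
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "stages": {},
        "warnings": [],
        "outputs": [],
    }

    def emit(name: str) -> str:
        manifest["outputs"].append(name)
        return os.path.join(out, name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- simulate or load -------------------------------------------------
        if cfg.input_dir:
            records = read_cohort(cfg.input_dir)
        else:
            synth_cfg = build_synth_config(cfg)
            records, reference = generate_cohort(synth_cfg)
            if cfg.write_records:
                os.makedirs(os.path.join(out, "records"), exist_ok=True)
                write_cohort(records, os.path.join(out, "records"))
                manifest["outputs"].append("records/")
            reference.to_csv(emit("reference.csv"), index=False)
        manifest["stages"]["simulate"] = {"n_records": len(records)}

        # --- preprocess: SNR bookkeeping --------------------------------------
        spec = FilterSpec(**cfg.filter)
        snr_rows = []
        for rec in records:
            clean = preprocess_record(rec, spec)
            snr_rows.append(
                {
                    "record_id": rec.record_id(),
                    "snr_raw_db": band_snr(rec).snr_db,
                    "snr_filtered_db": band_snr(clean).snr_db,
                }
            )
        snr = pd.DataFrame(snr_rows)
        snr.to_csv(emit("snr.csv"), index=False, float_format="%.6f")
        manifest["stages"]["preprocess"] = {
            "n_records": len(records),
            "mean_snr_gain_db": float((snr.snr_filtered_db - snr.snr_raw_db).mean()),
        }

        # --- features ---------------------------------------------------------
        extractor = WaveformFeatureExtractor(
            filter_order=spec.order,
            low_cut_hz=spec.low_cut_hz,
            high_cut_hz=spec.high_cut_hz,
            on_error="skip",
            **cfg.segmentation,
        )
        table = extractor.fit(records).transform(records)
        if table.empty:
            raise RuntimeError("feature extraction produced no rows")
        write_feature_table(table, emit("features.csv"))
        manifest["stages"]["features"] = {"n_records": int(len(table))}

        # --- feature prep -----------------------------------------------------
        # allow_empty: a no-signal cohort legitimately yields an empty shortlist;
        # the report and the run still complete (outlier fences then use every
        # feature column)
        selection = select_features(table, threshold=cfg.selection_threshold, allow_empty=True)
        selection.report().to_csv(emit("selection_report.csv"), index=False, float_format="%.6f")
        clean_table, removal_log = remove_outliers(
            table,
            feature_columns=selection.selected or list(FEATURE_COLUMNS),
            glucose_range=cfg.glucose_range,
            iqr_factor=cfg.iqr_factor,
        )
        removal_log.to_csv(emit("outliers_removed.csv"), index=False)
        write_feature_table(clean_table, emit("features_clean.csv"))
        engineered = FeatureEngineer().fit(clean_table).transform(clean_table[list(FEATURE_COLUMNS)])
        engineered_out = engineered.copy()
        engineered_out["glucose_mgdl"] = clean_table["glucose_mgdl"].to_numpy()
        engineered_out.to_csv(emit("engineered.csv"), index=False, float_format="%.15g")
        manifest["stages"]["prep"] = {
            "n_records": int(len(clean_table)),
            "n_selected_features": len(selection.selected),
            "n_outliers_removed": int(len(removal_log)),
        }

        # --- split / train / evaluate -----------------------------------------
        split = SplitSpec(
            train_fraction=cfg.train_fraction,
            seed=stage_seed(cfg.seed, "split"),
            grouping=cfg.grouping,
        )
        train, test = split_data(clean_table, split)
        pipe = build_model_pipeline(cfg)
        Xtr, ytr = train[list(FEATURE_COLUMNS)], train["glucose_mgdl"].to_numpy(dtype=float)
        Xte = test[list(FEATURE_COLUMNS)]
        pipe.fit(Xtr, ytr)
        pred = PredictionSet(
            actual=test["glucose_mgdl"].to_numpy(dtype=float),
            predicted=np.asarray(pipe.predict(Xte), dtype=float),
            subject_id=test["subject_id"].to_numpy(),
            state=test["state"].to_numpy(),
        )
        pred.to_frame().to_csv(emit("predictions.csv"), index=False, float_format="%.15g")
        rep = evaluate_metrics(pred)
        pd.DataFrame([dataclasses.asdict(rep)]).to_csv(
            emit("metrics.csv"), index=False, float_format="%.15g"
        )
        range_bias_frame(range_bias(pred)).to_csv(
            emit("range_bias.csv"), index=False, float_format="%.6f"
        )
        ba = bland_altman(pred)
        _write_json_atomic(dataclasses.asdict(ba), emit("bland_altman.json"))
        manifest["stages"]["model"] = {
            "n_train": int(len(train)),
            "n_test": int(len(test)),
            "metrics": dataclasses.asdict(rep),
        }

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    _write_json_atomic(manifest, os.path.join(out, "manifest.json"))
    manifest["outputs"].append("manifest.json")
    return manifest
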