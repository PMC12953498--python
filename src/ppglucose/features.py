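"""VPG/APG derivatives, a-e APG fiducials, and the 35-feature catalogue.

The velocity plethysmogram (VPG) is the first difference of the PPG and
the acceleration plethysmogram (APG) the second difference.  The APG of
one cardiac pulse carries five characteristic extrema: the early-systolic
maximum (a), the early-systolic minimum (b), the late-systolic
re-increase/re-decrease pair (c, d) and the early-diastolic maximum (e)
at the dicrotic notch.  The c and d waves are genuinely absent in some
pulses (shallow notch); their absence is flagged and propagated to the
ratio features that reference them.

The full feature vector per record comprises 35 values: seven
statistical descriptors (Min, Max, RMS, S_Energy, Mean, SD, Var) for
each of PPG/VPG/APG, six waveform-timing/amplitude features, and eight
APG amplitude ratios.  All are computed on three selected consecutive
pulses and averaged where applicable.

Two signals feed the computation: the band-passed trace (segmentation,
amplitude statistics) and the detrended trace smoothed with a 15 Hz
zero-phase low-pass (derivative fiducials) -- the 5 Hz band edge removes
most of the APG micro-structure, so fiducials cannot be read off the
band-passed signal reliably.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import MORPHOLOGY_LOWPASS_HZ, FilterSpec, bandpass_filter, detrend_signal, morphology_smooth
from .records import PPGRecord
from .segment import PulseSegment, SegmentationParams, pulse_rate, segment_pulses, select_consecutive, detect_fiducials


class FiducialError(ValueError):
    """Raised when the a-e waves of a pulse cannot be located."""


SIGNALS = ("ppg", "vpg", "apg")
STAT_NAMES = ("min", "max", "rms", "s_energy", "mean", "sd", "var")
WAVEFORM_COLUMNS = ("s_peak", "d_peak", "p_pint", "pulse_width", "p_rate", "t_interval")
RATIO_COLUMNS = (
    "b_over_a",
    "c_over_a",
    "d_over_a",
    "e_over_a",
    "b_minus_c_minus_d_minus_e_over_a",
    "b_minus_e_over_a",
    "b_minus_c_minus_d_over_a",
    "c_plus_d_minus_b_over_a",
)
#: Ratio features undefined when the c/d waves are absent.
CD_DEPENDENT_RATIOS = (
    "c_over_a",
    "d_over_a",
    "b_minus_c_minus_d_minus_e_over_a",
    "b_minus_c_minus_d_over_a",
    "c_plus_d_minus_b_over_a",
)
STAT_COLUMNS = tuple(f"{sig}_{stat}" for sig in SIGNALS for stat in STAT_NAMES)
FEATURE_COLUMNS = STAT_COLUMNS + WAVEFORM_COLUMNS + RATIO_COLUMNS
METADATA_COLUMNS = ("glucose_mgdl", "state", "subject_id")


def compute_vpg(y: np.ndarray, fs_hz: float | None = None) -> np.ndarray:
    """First difference y(t+1) - y(t); multiplied by fs when ``fs_hz`` given."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("VPG needs at least 2 samples")
    out = np.diff(y)
    return out * fs_hz if fs_hz else out


def compute_apg(y: np.ndarray, fs_hz: float | None = None) -> np.ndarray:
    """Second difference, evaluated as the first difference of the VPG
    (equal to y(t+1) + y(t-1) - 2 y(t)); times fs^2 when scaled."""
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("APG needs at least 3 samples")
    out = np.diff(y, 2)
    return out * fs_hz**2 if fs_hz else out


@dataclass
class DerivativeSet:
    """PPG with its difference-form derivatives (lengths n, n-1, n-2)."""

    ppg: np.ndarray
    vpg: np.ndarray
    apg: np.ndarray
    fs_hz: float

    @classmethod
    def from_signal(cls, y: np.ndarray, fs_hz: float, physical_units: bool = False) -> "DerivativeSet":
        scale = fs_hz if physical_units else None
        return cls(
            ppg=np.asarray(y, dtype=float),
            vpg=compute_vpg(y, scale),
            apg=compute_apg(y, fs_hz if physical_units else None),
            fs_hz=fs_hz,
        )


@dataclass
class FiducialSet:
    """a-e APG wave locations for one pulse.

    Indices are on the pulse's sample axis (APG sample t maps to PPG
    sample t+1).  ``c``/``d`` are ``None`` when flagged absent.
    """

    a: tuple[int, float]
    b: tuple[int, float]
    e: tuple[int, float]
    c: tuple[int, float] | None = None
    d: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        order = [self.a[0], self.b[0]]
        if self.has_cd:
            order += [self.c[0], self.d[0]]
        order.append(self.e[0])
        if not all(x < y for x, y in zip(order[:-1], order[1:])):
            raise FiducialError(f"APG wave ordering violated: {order}")

    @property
    def has_cd(self) -> bool:
        return self.c is not None and self.d is not None


def detect_apg_waves(
    pulse: PulseSegment,
    derivatives: DerivativeSet,
    c_prominence_fraction: float = 0.1,
) -> FiducialSet:
    """Locate the a, b, (c, d,) e waves on one pulse's APG.

    a is the largest positive APG local maximum at or before the systolic
    peak; b the deepest minimum after a; e the largest positive maximum
    after b (the dicrotic-notch curvature peak); c is the largest interior
    maximum between b and e exceeding ``c_prominence_fraction`` of the
    e-wave amplitude, with d the deepest minimum between c and e.  c and d
    are flagged absent when no such pair exists.
    """
    apg = derivatives.apg
    ppg = derivatives.ppg
    sp = pulse.peak_offset
    amx = argrelextrema(apg, np.greater)[0]
    amn = argrelextrema(apg, np.less)[0]

    def at(i: int) -> tuple[int, float]:
        # APG sample i corresponds to PPG sample i+1 of the pulse
        return (int(i) + 1, float(apg[i]))

    a_cand = [i for i in amx if i + 1 <= sp and apg[i] > 0]
    if not a_cand:
        raise FiducialError("undetectable fiducials: no positive APG maximum in the systolic half")
    a = max(a_cand, key=lambda i: apg[i])
    b_cand = [i for i in amn if i > a]
    if not b_cand:
        raise FiducialError("undetectable fiducials: no APG minimum after the a wave")
    b = min(b_cand, key=lambda i: apg[i])
    e_cand = [i for i in amx if i > b and apg[i] > 0]
    if not e_cand:
        raise FiducialError("undetectable fiducials: no positive APG maximum after the b wave")
    e = max(e_cand, key=lambda i: apg[i])

    c = d = None
    mid = [i for i in amx if b < i < e and apg[i] > c_prominence_fraction * apg[e]]
    if mid:
        c_i = max(mid, key=lambda i: apg[i])
        dd = [i for i in amn if c_i < i < e]
        if dd:
            c = c_i
            d = min(dd, key=lambda i: apg[i])
    return FiducialSet(
        a=at(a),
        b=at(b),
        e=at(e),
        c=at(c) if c is not None else None,
        d=at(d) if d is not None else None,
    )


def apg_ratios(f: FiducialSet) -> dict[str, float]:
    """The eight APG amplitude ratios; absent c/d propagate as NaN."""
    a = f.a[1]
    if a == 0:
        raise FiducialError("a-wave amplitude is zero; ratios undefined")
    b, e = f.b[1], f.e[1]
    c = f.c[1] if f.c is not None else np.nan
    d = f.d[1] if f.d is not None else np.nan
    return {
        "b_over_a": b / a,
        "c_over_a": c / a,
        "d_over_a": d / a,
        "e_over_a": e / a,
        "b_minus_c_minus_d_minus_e_over_a": (b - c - d - e) / a,
        "b_minus_e_over_a": (b - e) / a,
        "b_minus_c_minus_d_over_a": (b - c - d) / a,
        "c_plus_d_minus_b_over_a": (c + d - b) / a,
    }


def statistical_features(series: np.ndarray) -> dict[str, float]:
    """Min, Max, RMS, signal energy, mean, sample SD and variance."""
    y = np.asarray(series, dtype=float)
    if y.size < 2:
        raise ValueError("statistical features need at least 2 samples")
    return {
        "min": float(np.min(y)),
        "max": float(np.max(y)),
        "rms": float(np.sqrt(np.mean(y**2))),
        "s_energy": float(np.sum(y**2)),
        "mean": float(np.mean(y)),
        "sd": float(np.std(y, ddof=1)),
        "var": float(np.var(y, ddof=1)),
    }


def _diastolic_peak(
    morph_pulse: np.ndarray, fiducials: FiducialSet, peak_offset: int
) -> tuple[int, float, bool]:
    """Diastolic peak: first PPG local max after the e wave.

    Fallback (flagged): the PPG inflection after the systolic peak, i.e.
    the VPG local maximum, when no diastolic local maximum exists.
    """
    e_idx = fiducials.e[0]
    maxima = argrelextrema(morph_pulse, np.greater)[0]
    after = maxima[maxima > e_idx]
    if after.size:
        i = int(after[0])
        return i, float(morph_pulse[i]), False
    vpg = np.diff(morph_pulse)
    vmx = argrelextrema(vpg, np.greater)[0]
    vafter = vmx[vmx > peak_offset]
    if vafter.size:
        i = int(vafter[0]) + 1
        return i, float(morph_pulse[i]), True
    raise FiducialError("no diastolic peak or inflection found after the systolic peak")


@dataclass
class WaveformFeatures:
    """Averaged per-pulse timing and amplitude features (times in s)."""

    s_peak: float
    d_peak: float
    p_pint: float
    pulse_width: float
    p_rate: float
    t_interval: float


def waveform_features(
    selected: list[PulseSegment],
    morph_pulses: list[np.ndarray],
    fiducials: list[FiducialSet],
    fs_hz: float,
    record_peaks: np.ndarray,
) -> WaveformFeatures:
    """Averaged waveform features over the selected pulses.

    Amplitudes (S_Peak, D_Peak) are read off the morphology-smoothed
    pulses relative to the pulse foot (the pulse minimum), making them
    invariant to the DC level the band-pass removes.  Intervals come from
    the pulse/peak indices.  D_Peak failures in a subset of pulses
    average over the available ones with a warning.
    """
    feet = [float(np.min(mp)) for mp in morph_pulses]
    s_peaks = [float(np.max(mp)) - foot for mp, foot in zip(morph_pulses, feet)]
    d_vals: list[float] = []
    d_abs_idx: list[int] = []
    for seg, mp, fid, foot in zip(selected, morph_pulses, fiducials, feet):
        try:
            i, v, flagged = _diastolic_peak(mp, fid, seg.peak_offset)
            if flagged:
                warnings.warn("diastolic peak absent; used PPG inflection", RuntimeWarning, stacklevel=2)
            d_vals.append(v - foot)
            d_abs_idx.append(seg.start_index + i)
        except FiducialError:
            continue
    if not d_vals:
        raise FiducialError("diastolic peak missing in every selected pulse")
    if len(d_vals) < len(selected):
        warnings.warn(
            f"diastolic peak found in {len(d_vals)}/{len(selected)} pulses; averaging the rest",
            RuntimeWarning,
            stacklevel=2,
        )
    peak_idx = [seg.systolic_peak_index for seg in selected]
    p_pint = float(np.mean(np.diff(peak_idx)) / fs_hz)
    widths = [seg.duration_s(fs_hz) for seg in selected]
    t_interval = (
        float(np.mean(np.diff(d_abs_idx)) / fs_hz) if len(d_abs_idx) >= 2 else float("nan")
    )
    return WaveformFeatures(
        s_peak=float(np.mean(s_peaks)),
        d_peak=float(np.mean(d_vals)),
        p_pint=p_pint,
        pulse_width=float(np.mean(widths)),
        p_rate=pulse_rate(record_peaks, fs_hz),
        t_interval=t_interval,
    )


def assemble_feature_vector(
    record: PPGRecord,
    selected: list[PulseSegment],
    morph_signal: np.ndarray,
    record_peaks: np.ndarray,
    per_pulse_stats: bool = False,
    physical_units: bool = False,
    c_prominence_fraction: float = 0.1,
) -> dict[str, float]:
    """All 35 features plus record metadata for one record.

    Statistical features are computed on the concatenated three-pulse
    PPG/VPG/APG of the band-passed signal (per-pulse-then-average behind
    ``per_pulse_stats``); fiducial features on the morphology-smoothed
    signal; ratios averaged over the pulses where they are defined.
    """
    fs = record.fs_hz
    morph_pulses = [morph_signal[s.start_index : s.end_index] for s in selected]
    fiducials = []
    for mp, seg in zip(morph_pulses, selected):
        deriv = DerivativeSet.from_signal(mp, fs, physical_units=physical_units)
        fiducials.append(detect_apg_waves(seg, deriv, c_prominence_fraction))

    row: dict[str, float] = {}
    if per_pulse_stats:
        per_sig: dict[str, list[dict[str, float]]] = {s: [] for s in SIGNALS}
        for seg in selected:
            d = DerivativeSet.from_signal(seg.samples, fs, physical_units=physical_units)
            for sig in SIGNALS:
                per_sig[sig].append(statistical_features(getattr(d, sig)))
        for sig in SIGNALS:
            for stat in STAT_NAMES:
                row[f"{sig}_{stat}"] = float(np.mean([p[stat] for p in per_sig[sig]]))
    else:
        concat = np.concatenate([s.samples for s in selected])
        d = DerivativeSet.from_signal(concat, fs, physical_units=physical_units)
        for sig in SIGNALS:
            stats = statistical_features(getattr(d, sig))
            for stat in STAT_NAMES:
                row[f"{sig}_{stat}"] = stats[stat]

    wf = waveform_features(selected, morph_pulses, fiducials, fs, record_peaks)
    row.update(
        s_peak=wf.s_peak,
        d_peak=wf.d_peak,
        p_pint=wf.p_pint,
        pulse_width=wf.pulse_width,
        p_rate=wf.p_rate,
        t_interval=wf.t_interval,
    )

    ratio_rows = [apg_ratios(f) for f in fiducials]
    for name in RATIO_COLUMNS:
        vals = np.asarray([r[name] for r in ratio_rows], dtype=float)
        defined = vals[np.isfinite(vals)]
        row[name] = float(np.mean(defined)) if defined.size else float("nan")

    row["glucose_mgdl"] = record.glucose_mgdl
    row["state"] = record.state
    row["subject_id"] = record.subject_id
    return row


class WaveformFeatureExtractor(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: list of PPG records -> feature table.

    For each record: detrend + band-pass (skipped when the record's
    provenance shows it already applied), segment into pulses, select
    ``k`` consecutive pulses, smooth the detrended trace at
    ``morphology_cutoff_hz`` for derivative fiducials, and assemble the
    35-column feature vector.  Records that fail a stage raise by default
    (``on_error="skip"`` drops them with a warning).
    """

    def __init__(
        self,
        filter_order: int = 2,
        low_cut_hz: float = 0.5,
        high_cut_hz: float = 5.0,
        min_period_s: float = 0.6,
        max_period_s: float = 1.0,
        min_prominence_fraction: float = 0.3,
        k_pulses: int = 3,
        morphology_cutoff_hz: float = MORPHOLOGY_LOWPASS_HZ,
        per_pulse_stats: bool = False,
        physical_units: bool = False,
        c_prominence_fraction: float = 0.1,
        on_error: str = "raise",
    ):
        self.filter_order = filter_order
        self.low_cut_hz = low_cut_hz
        self.high_cut_hz = high_cut_hz
        self.min_period_s = min_period_s
        self.max_period_s = max_period_s
        self.min_prominence_fraction = min_prominence_fraction
        self.k_pulses = k_pulses
        self.morphology_cutoff_hz = morphology_cutoff_hz
        self.per_pulse_stats = per_pulse_stats
        self.physical_units = physical_units
        self.c_prominence_fraction = c_prominence_fraction
        self.on_error = on_error

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def _extract_one(self, record: PPGRecord) -> dict[str, float]:
        if any(p.startswith("bandpass") for p in record.provenance):
            filtered = record
            detrended = record.extras.get("detrended", record.samples)
        else:
            detr = detrend_signal(record)
            spec = FilterSpec(
                order=self.filter_order,
                low_cut_hz=self.low_cut_hz,
                high_cut_hz=self.high_cut_hz,
                zero_phase=True,
            )
            filtered = bandpass_filter(detr, spec)
            detrended = detr.samples
        params = SegmentationParams(
            min_period_s=self.min_period_s,
            max_period_s=self.max_period_s,
            min_prominence_fraction=self.min_prominence_fraction,
        )
        peaks, valleys = detect_fiducials(filtered, params)
        segments = segment_pulses(filtered, valleys)
        selected = select_consecutive(segments, self.k_pulses)
        morph = morphology_smooth(detrended, record.fs_hz, self.morphology_cutoff_hz)
        return assemble_feature_vector(
            filtered,
            selected,
            morph,
            peaks,
            per_pulse_stats=self.per_pulse_stats,
            physical_units=self.physical_units,
            c_prominence_fraction=self.c_prominence_fraction,
        )

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for rec in X:
            try:
                rows.append(self._extract_one(rec))
            except (ValueError, FiducialError) as exc:
                if self.on_error == "skip":
                    warnings.warn(f"{rec.record_id()}: {exc}", RuntimeWarning, stacklevel=2)
                    continue
                raise type(exc)(f"{rec.record_id()}: {exc}") from exc
        table = pd.DataFrame(rows)
        if not table.empty:
            table = table[list(FEATURE_COLUMNS) + list(METADATA_COLUMNS)]
        return table


def extract_feature_table(records: list[PPGRecord], **kwargs) -> pd.DataFrame:
    """Thin functional wrapper over :class:`WaveformFeatureExtractor`."""
    return WaveformFeatureExtractor(**kwargs).fit(records).transform(records)


def write_feature_table(table: pd.DataFrame, path: str) -> None:
    """Write the standardized feature CSV (canonical column order)."""
    missing = [c for c in FEATURE_COLUMNS + METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing canonical columns: {missing}")
    extra = [c for c in table.columns if c not in FEATURE_COLUMNS + METADATA_COLUMNS]
    if extra:
        warnings.warn(f"preserving non-canonical columns: {extra}", RuntimeWarning, stacklevel=2)
    cols = list(FEATURE_COLUMNS) + extra + list(METADATA_COLUMNS)
    # %.17g is lossless for IEEE doubles (comfortably past 15 significant digits)
    table[cols].to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    if "glucose_mgdl" not in table.columns:
        raise ValueError(f"{path}: missing required 'glucose_mgdl' column")
    return table
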