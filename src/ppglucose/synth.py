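"""Seeded synthetic PPG cohort generator.

Emulates the acquisition statistics of an 80-subject fasting/postprandial
finger-PPG study: 15 s single-channel records sampled at ~127 Hz, paired
reference glucose readings (fasting 93 +/- 22 mg/dL, postprandial
113 +/- 30 mg/dL, truncated by rejection to the 65-160 mg/dL inclusion
range), per-subject heart rate uniform on 60-100 bpm, and realistic
noise (baseline drift, mains interference, white noise, transient
motion bursts).

Each cardiac beat is a two-component template -- a systolic Gaussian plus
a delayed, wider diastolic Gaussian -- with a narrow subtractive Gaussian
at the inter-peak minimum realising the dicrotic notch.  The notch term
is what gives the second derivative (APG) its characteristic
a-b-c-d-e wave pattern.  Blood glucose is coupled to the beat morphology
linearly (configurable slope per mg/dL on each morphology parameter);
the coupling is a statistical stand-in, not a hemodynamic model.

Every record carries ground truth: planted beat onsets, systolic peak
indices (the argmax of the noise-free trace within each beat window) and
dicrotic notch indices.  The whole cohort is a pure function of the
configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import VALID_STATES, GroundTruth, PPGRecord


class SynthConfigError(ValueError):
    """Raised for physically impossible or inconsistent generator settings."""


@dataclass
class MorphologyParams:
    """Shape of one cardiac beat (amplitudes in arbitrary units, times in s).

    ``systolic_amplitude`` scales the whole beat; the diastolic wave is a
    fraction of it, delayed by ``diastolic_delay_s``; the dicrotic notch
    is a narrow dip of depth ``notch_depth_fraction`` x systolic amplitude
    placed at the minimum between the two component peaks.
    """

    systolic_amplitude: float = 1.0
    systolic_width_s: float = 0.08
    diastolic_amplitude_fraction: float = 0.42
    diastolic_delay_s: float = 0.33
    notch_depth_fraction: float = 0.12
    notch_width_s: float = 0.025
    systolic_center_s: float = 0.18
    diastolic_width_ratio: float = 1.2

    def validate(self) -> None:
        for name in (
            "systolic_amplitude",
            "systolic_width_s",
            "diastolic_delay_s",
            "notch_width_s",
            "systolic_center_s",
            "diastolic_width_ratio",
        ):
            if not getattr(self, name) > 0:
                raise SynthConfigError(f"{name} must be strictly positive")
        if not 0 < self.diastolic_amplitude_fraction < 1:
            raise SynthConfigError("diastolic_amplitude_fraction must lie in (0,1)")
        if self.notch_depth_fraction < 0:
            raise SynthConfigError("notch_depth_fraction must be >= 0")


@dataclass
class NoiseConfig:
    """Additive disturbances; all amplitudes in the same units as the beat."""

    baseline_drift_amplitude: float = 0.3
    baseline_drift_frequency_hz: float = 0.2
    powerline_frequency_hz: float = 50.0
    powerline_amplitude: float = 0.02
    white_noise_sd: float = 0.01
    motion_artifact_rate_per_min: float = 2.0
    motion_artifact_amplitude: float = 0.8
    motion_artifact_duration_s: float = 0.5

    def validate(self) -> None:
        for name in (
            "baseline_drift_amplitude",
            "powerline_amplitude",
            "white_noise_sd",
            "motion_artifact_rate_per_min",
            "motion_artifact_amplitude",
            "motion_artifact_duration_s",
        ):
            if getattr(self, name) < 0:
                raise SynthConfigError(f"{name} must be >= 0")
        if not self.baseline_drift_frequency_hz < 0.5:
            raise SynthConfigError("baseline drift must stay below the 0.5 Hz analysis band")

    def is_silent(self) -> bool:
        return (
            self.baseline_drift_amplitude == 0
            and self.powerline_amplitude == 0
            and self.white_noise_sd == 0
            and self.motion_artifact_rate_per_min == 0
        )

    @classmethod
    def silent(cls) -> "NoiseConfig":
        return cls(
            baseline_drift_amplitude=0.0,
            powerline_amplitude=0.0,
            white_noise_sd=0.0,
            motion_artifact_rate_per_min=0.0,
        )


# Glucose -> morphology coupling, slope per mg/dL about the 100 mg/dL pivot.
# The magnitudes are stand-ins (no published quantitative effect sizes exist);
# they are sized against the per-subject morphology variability so that the
# planted signal is recoverable by the pipeline-end regression.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "systolic_amplitude": 5.0e-3,
    "diastolic_amplitude_fraction": 2.0e-3,
    "diastolic_delay_s": 6.0e-4,
    "notch_depth_fraction": 4.0e-4,
}

GLUCOSE_PIVOT_MGDL = 100.0

# Per-subject morphology jitter (SD of Gaussian perturbations of the template),
# the main confound the regression has to average out.
SUBJECT_JITTER_SD: dict[str, float] = {
    "systolic_amplitude": 0.03,
    "diastolic_amplitude_fraction": 0.01,
    "diastolic_delay_s": 0.008,
}


@dataclass
class SubjectProfile:
    """Per-subject physiology: identifier, age, heart rate, paired glucose."""

    subject_id: str
    age_years: int
    heart_rate_bpm: float
    fasting_glucose_mgdl: float
    postprandial_glucose_mgdl: float
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    phase_s: float = 0.0


@dataclass
class SynthConfig:
    """Full cohort description; the cohort is a pure function of this object."""

    n_subjects: int = 80
    fs_hz: float = 127.0
    duration_s: float = 15.0
    fasting_mean_mgdl: float = 93.0
    fasting_sd_mgdl: float = 22.0
    postprandial_mean_mgdl: float = 113.0
    postprandial_sd_mgdl: float = 30.0
    glucose_min_mgdl: float = 65.0
    glucose_max_mgdl: float = 160.0
    heart_rate_range_bpm: tuple[float, float] = (60.0, 100.0)
    age_range_years: tuple[int, int] = (18, 50)
    glucose_effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    subject_jitter_sd: dict[str, float] = field(
        default_factory=lambda: dict(SUBJECT_JITTER_SD)
    )
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 42

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SynthConfigError("n_subjects must be >= 1")
        if not self.fs_hz > 2 * 5.0:
            raise SynthConfigError("fs_hz must exceed twice the 5 Hz analysis band edge")
        if self.glucose_min_mgdl >= self.glucose_max_mgdl:
            raise SynthConfigError("glucose inclusion range is empty or inverted")
        lo, hi = self.heart_rate_range_bpm
        if not 0 < lo < hi:
            raise SynthConfigError("heart_rate_range_bpm must be an increasing positive pair")
        if self.duration_s * lo / 60.0 < 3:
            raise SynthConfigError("duration too short: fewer than 3 pulses at the minimum heart rate")
        # the narrowest morphology feature must be resolvable at fs
        if self.morphology.notch_width_s * self.fs_hz < 2:
            raise SynthConfigError("fs_hz too low for the requested notch width")
        unknown = set(self.glucose_effect_sizes) - {
            f.name for f in MorphologyParams.__dataclass_fields__.values()  # type: ignore[attr-defined]
        }
        if unknown:
            raise SynthConfigError(f"glucose_effect_sizes refers to unknown morphology fields: {sorted(unknown)}")
        self.morphology.validate()
        self.noise.validate()


def sample_glucose(config: SynthConfig, state: str, rng: np.random.Generator) -> float:
    """Draw one reference glucose value (mg/dL) for the given state.

    Normal draw with the state's mean/SD, rejection-sampled into the
    inclusion range (no probability mass piles up at the range edges).
    """
    if state not in VALID_STATES:
        raise ValueError(f"state must be one of {VALID_STATES}")
    config.validate()
    if state == "fasting":
        mean, sd = config.fasting_mean_mgdl, config.fasting_sd_mgdl
    else:
        mean, sd = config.postprandial_mean_mgdl, config.postprandial_sd_mgdl
    lo, hi = config.glucose_min_mgdl, config.glucose_max_mgdl
    if sd == 0:
        if not lo <= mean <= hi:
            raise SynthConfigError("degenerate glucose distribution lies outside the inclusion range")
        return float(mean)
    for _ in range(100_000):
        g = rng.normal(mean, sd)
        if lo <= g <= hi:
            return float(g)
    raise SynthConfigError("rejection sampling failed: inclusion range has negligible mass")


def _effective_morphology(
    base: MorphologyParams, effect_sizes: dict[str, float], glucose_mgdl: float
) -> MorphologyParams:
    """Shift morphology linearly with glucose about the pivot, then clamp
    to validity."""
    changes = {}
    for name, slope in effect_sizes.items():
        changes[name] = getattr(base, name) + slope * (glucose_mgdl - GLUCOSE_PIVOT_MGDL)
    params = replace(base, **changes)
    # clamp to physical validity; slopes are small enough that this rarely binds
    params = replace(
        params,
        systolic_amplitude=max(params.systolic_amplitude, 0.05),
        diastolic_amplitude_fraction=min(max(params.diastolic_amplitude_fraction, 0.05), 0.95),
        diastolic_delay_s=max(params.diastolic_delay_s, 0.05),
        notch_depth_fraction=max(params.notch_depth_fraction, 0.0),
    )
    params.validate()
    return params


def _notch_center_s(m: MorphologyParams) -> float:
    """Location of the dicrotic notch: the minimum of the two-Gaussian sum
    between the systolic and diastolic component centres."""
    t = np.linspace(m.systolic_center_s + 1e-3, m.systolic_center_s + m.diastolic_delay_s, 512)
    sys_w, dia_w = m.systolic_width_s, m.systolic_width_s * m.diastolic_width_ratio
    base = np.exp(-0.5 * ((t - m.systolic_center_s) / sys_w) ** 2) + (
        m.diastolic_amplitude_fraction
        * np.exp(-0.5 * ((t - m.systolic_center_s - m.diastolic_delay_s) / dia_w) ** 2)
    )
    return float(t[np.argmin(base)])


def _beat_components(t: np.ndarray, onset_s: float, m: MorphologyParams) -> np.ndarray:
    """Evaluate one beat's template (all three Gaussian components) on ``t``."""
    a = m.systolic_amplitude
    sys_c = onset_s + m.systolic_center_s
    dia_c = sys_c + m.diastolic_delay_s
    sys_w = m.systolic_width_s
    dia_w = sys_w * m.diastolic_width_ratio
    notch_c = onset_s + _notch_center_s(m)
    y = a * np.exp(-0.5 * ((t - sys_c) / sys_w) ** 2)
    y += a * m.diastolic_amplitude_fraction * np.exp(-0.5 * ((t - dia_c) / dia_w) ** 2)
    y -= a * m.notch_depth_fraction * np.exp(-0.5 * ((t - notch_c) / m.notch_width_s) ** 2)
    return y


#: Reference cardiac period the morphology time constants are stated at
#: (72 bpm); at other heart rates all time constants scale with the period,
#: mirroring the shortening of systole as heart rate rises.
REF_PERIOD_S = 60.0 / 72.0


def _scale_to_period(m: MorphologyParams, period_s: float) -> MorphologyParams:
    s = period_s / REF_PERIOD_S
    return replace(
        m,
        systolic_width_s=m.systolic_width_s * s,
        diastolic_delay_s=m.diastolic_delay_s * s,
        notch_width_s=m.notch_width_s * s,
        systolic_center_s=m.systolic_center_s * s,
    )


def _clean_signal(
    t: np.ndarray, period_s: float, phase_s: float, m: MorphologyParams, duration_s: float
) -> tuple[np.ndarray, list[float], float]:
    """Noise-free periodic beat train; returns (signal, beat onsets >= 0, notch offset)."""
    m = _scale_to_period(m, period_s)
    y = np.zeros_like(t)
    onsets: list[float] = []
    # beats whose support can touch the record, including partial edge beats
    k0 = int(np.floor((-phase_s - period_s) / period_s)) - 1
    k1 = int(np.ceil((duration_s + period_s) / period_s)) + 1
    for k in range(k0, k1 + 1):
        onset = phase_s + k * period_s
        if onset + 2 * period_s < 0 or onset - period_s > duration_s:
            continue
        y += _beat_components(t, onset, m)
        if 0 <= onset and onset + period_s <= duration_s + 1e-9:
            onsets.append(onset)
    return y, onsets, _notch_center_s(m)


def _interior_argmax(y: np.ndarray, lo: int, hi: int) -> int | None:
    """Argmax of y[lo:hi] if it is a strict interior local maximum of y."""
    if hi - lo < 3:
        return None
    i = lo + int(np.argmax(y[lo:hi]))
    if 1 <= i <= y.size - 2 and y[i] >= y[i - 1] and y[i] >= y[i + 1] and 2 <= i <= y.size - 3:
        return i
    return None


def synthesize_record(
    profile: SubjectProfile,
    state: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> PPGRecord:
    """Generate one 15 s record for a subject in the given state."""
    if state not in VALID_STATES:
        raise ValueError(f"state must be one of {VALID_STATES}")
    lo_hr, hi_hr = config.heart_rate_range_bpm
    if not lo_hr <= profile.heart_rate_bpm <= hi_hr:
        raise SynthConfigError(
            f"heart rate {profile.heart_rate_bpm} bpm outside configured range {config.heart_rate_range_bpm}"
        )
    glucose = (
        profile.fasting_glucose_mgdl if state == "fasting" else profile.postprandial_glucose_mgdl
    )
    m = _effective_morphology(profile.morphology, config.glucose_effect_sizes, glucose)
    fs = config.fs_hz
    n = int(round(fs * config.duration_s))
    t = np.arange(n) / fs
    period = 60.0 / profile.heart_rate_bpm

    clean, onsets, notch_off = _clean_signal(t, period, profile.phase_s, m, config.duration_s)

    # planted systolic peaks: argmax of the clean trace within each beat window,
    # kept only when it is an interior local maximum; partial edge beats count
    # as long as their systolic peak itself lies inside the record, since a
    # detector sees those peaks too
    peaks: list[int] = []
    notches: list[int] = []
    k_first = int(np.ceil((-profile.phase_s) / period)) - 1
    k_last = int(np.floor((config.duration_s - profile.phase_s) / period)) + 1
    for k in range(k_first, k_last + 1):
        onset = profile.phase_s + k * period
        lo = max(0, int(round(onset * fs)))
        hi = min(n, int(round((onset + period) * fs)))
        if hi <= lo:
            continue
        p = _interior_argmax(clean, lo, hi)
        if p is not None:
            peaks.append(p)
            notch_i = int(round((onset + notch_off) * fs))
            if 0 <= notch_i < n:
                notches.append(notch_i)

    y = clean.copy()
    noise = config.noise
    # noise draws happen unconditionally so the rng stream does not depend on
    # the amplitude values (zero-amplitude noise reproduces the clean trace
    # under the same stream)
    drift_phase = rng.uniform(0, 2 * np.pi)
    y += noise.baseline_drift_amplitude * np.sin(
        2 * np.pi * noise.baseline_drift_frequency_hz * t + drift_phase
    )
    mains_phase = rng.uniform(0, 2 * np.pi)
    y += noise.powerline_amplitude * np.sin(2 * np.pi * noise.powerline_frequency_hz * t + mains_phase)
    y += noise.white_noise_sd * rng.standard_normal(n)
    # transient motion bursts at Poisson times: Gaussian-windowed in-band wobble
    n_bursts = rng.poisson(noise.motion_artifact_rate_per_min * config.duration_s / 60.0)
    for _ in range(n_bursts):
        tc = rng.uniform(0, config.duration_s)
        f_burst = rng.uniform(2.0, 4.0)
        ph = rng.uniform(0, 2 * np.pi)
        envelope = np.exp(-0.5 * ((t - tc) / (noise.motion_artifact_duration_s / 4)) ** 2)
        y += noise.motion_artifact_amplitude * envelope * np.sin(2 * np.pi * f_burst * t + ph)

    gt = GroundTruth(
        beat_onsets=np.round(np.asarray(onsets) * fs).astype(int),
        systolic_peaks=np.asarray(peaks, dtype=int),
        notches=np.asarray(notches, dtype=int),
    )
    return PPGRecord(
        samples=y,
        fs_hz=fs,
        subject_id=profile.subject_id,
        state=state,
        glucose_mgdl=glucose,
        ground_truth=gt,
        provenance=["synth"],
    )


def sample_subject(config: SynthConfig, index: int, rng: np.random.Generator) -> SubjectProfile:
    """Draw one subject: age, heart rate, paired glucose, morphology baseline."""
    age = int(rng.integers(config.age_range_years[0], config.age_range_years[1] + 1))
    hr = float(rng.uniform(*config.heart_rate_range_bpm))
    fasting = sample_glucose(config, "fasting", rng)
    for _ in range(1000):
        post = sample_glucose(config, "postprandial", rng)
        if post >= fasting - 10.0:
            break
    else:  # pragma: no cover - requires pathological config
        raise SynthConfigError("could not draw a postprandial value >= fasting - 10")
    jitter = {
        name: float(rng.normal(0.0, sd)) for name, sd in config.subject_jitter_sd.items()
    }
    morph = replace(
        config.morphology,
        **{name: getattr(config.morphology, name) + dj for name, dj in jitter.items()},
    )
    morph = replace(
        morph,
        systolic_amplitude=max(morph.systolic_amplitude, 0.05),
        diastolic_amplitude_fraction=min(max(morph.diastolic_amplitude_fraction, 0.05), 0.95),
        diastolic_delay_s=max(morph.diastolic_delay_s, 0.05),
    )
    phase = float(rng.uniform(0, 60.0 / hr))
    return SubjectProfile(
        subject_id=f"S{index:03d}",
        age_years=age,
        heart_rate_bpm=hr,
        fasting_glucose_mgdl=fasting,
        postprandial_glucose_mgdl=post,
        morphology=morph,
        phase_s=phase,
    )


def generate_cohort(config: SynthConfig) -> tuple[list[PPGRecord], pd.DataFrame]:
    """Generate the full cohort: two records (fasting + postprandial) per subject.

    Returns the record list and a reference table with one row per record
    (``subject_id, state, glucose_mgdl, heart_rate_bpm, age_years``).
    Identical configs (including seed) produce identical cohorts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[PPGRecord] = []
    rows = []
    for i in range(config.n_subjects):
        profile = sample_subject(config, i, rng)
        for state in VALID_STATES:
            rec = synthesize_record(profile, state, config, rng)
            records.append(rec)
            rows.append(
                {
                    "subject_id": profile.subject_id,
                    "state": state,
                    "glucose_mgdl": rec.glucose_mgdl,
                    "heart_rate_bpm": profile.heart_rate_bpm,
                    "age_years": profile.age_years,
                }
            )
    return records, pd.DataFrame(rows)
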