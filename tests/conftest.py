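"""Shared fixtures: seeded synthetic cohorts and per-record helpers."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ppglucose import (
    MorphologyParams,
    PPGRecord,
    SubjectProfile,
    SynthConfig,
    WaveformFeatureExtractor,
    generate_cohort,
    synthesize_record,
)
from ppglucose.preprocess import bandpass_filter, detrend_signal, morphology_smooth
from ppglucose.segment import detect_fiducials, segment_pulses, select_consecutive
from ppglucose.synth import NoiseConfig


@pytest.fixture(scope="session")
def clean_cohort():
    """20 noise-free records (10 subjects), heart rates uniform on 60-100."""
    cfg = SynthConfig(n_subjects=10, noise=NoiseConfig.silent(), seed=55)
    records, reference = generate_cohort(cfg)
    return records, reference


@pytest.fixture(scope="session")
def noisy_cohort():
    """24 records under the default noise model."""
    cfg = SynthConfig(n_subjects=12, seed=101)
    records, reference = generate_cohort(cfg)
    return records, reference


@pytest.fixture(scope="session")
def feature_table(noisy_cohort):
    records, _ = noisy_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return WaveformFeatureExtractor(on_error="skip").fit(records).transform(records)


@pytest.fixture()
def clean_record_60bpm():
    """One noise-free record at exactly 60 bpm, zero phase offset."""
    cfg = SynthConfig(n_subjects=1, noise=NoiseConfig.silent(), seed=0)
    profile = SubjectProfile(
        subject_id="fix60",
        age_years=30,
        heart_rate_bpm=60.0,
        fasting_glucose_mgdl=100.0,
        postprandial_glucose_mgdl=120.0,
        morphology=MorphologyParams(),
        phase_s=0.0,
    )
    return synthesize_record(profile, "fasting", cfg, np.random.default_rng(0))


@pytest.fixture()
def clean_record_72bpm():
    cfg = SynthConfig(n_subjects=1, noise=NoiseConfig.silent(), seed=0)
    profile = SubjectProfile(
        subject_id="fix72",
        age_years=30,
        heart_rate_bpm=72.0,
        fasting_glucose_mgdl=100.0,
        postprandial_glucose_mgdl=120.0,
        morphology=MorphologyParams(),
        phase_s=0.0,
    )
    return synthesize_record(profile, "fasting", cfg, np.random.default_rng(0))


def make_record(samples, fs_hz=127.0, **kwargs) -> PPGRecord:
    return PPGRecord(samples=np.asarray(samples, dtype=float), fs_hz=fs_hz, **kwargs)


def prepare_pulses(record: PPGRecord, k: int = 3):
    """Run the canonical per-record chain used by the feature stage.

    Returns (filtered record, selected pulses, morphology signal, peaks).
    """
    detr = detrend_signal(record)
    filt = bandpass_filter(detr)
    peaks, valleys = detect_fiducials(filt)
    segments = segment_pulses(filt, valleys)
    selected = select_consecutive(segments, k)
    morph = morphology_smooth(detr.samples, record.fs_hz)
    return filt, selected, morph, peaks
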