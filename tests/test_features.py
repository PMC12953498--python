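"""Derivative oracles, a-e fiducials, ratios and the 35-feature vector."""

from __future__ import annotations

import numpy as np
import pytest

from ppglucose import (
    DerivativeSet,
    FiducialSet,
    MorphologyParams,
    SynthConfig,
    WaveformFeatureExtractor,
    apg_ratios,
    assemble_feature_vector,
    compute_apg,
    compute_vpg,
    detect_apg_waves,
    generate_cohort,
    statistical_features,
)
from ppglucose.features import (
    FEATURE_COLUMNS,
    METADATA_COLUMNS,
    RATIO_COLUMNS,
    FiducialError,
    waveform_features,
)
from ppglucose.synth import NoiseConfig

from conftest import prepare_pulses


def vpg_oracle(y):
    return np.array([y[i + 1] - y[i] for i in range(len(y) - 1)])


def apg_oracle(y):
    # difference of the velocity series, the form the APG is derived in
    # (equal to y[i+1] + y[i-1] - 2 y[i] in exact arithmetic)
    return np.array([(y[i + 1] - y[i]) - (y[i] - y[i - 1]) for i in range(1, len(y) - 1)])


class TestDerivatives:
    def test_vpg_ramp_and_constant(self):
        np.testing.assert_array_equal(compute_vpg([0, 1, 2, 3]), [1, 1, 1])
        np.testing.assert_array_equal(compute_vpg(np.full(10, 2.5)), np.zeros(9))

    def test_apg_quadratic_and_linear(self):
        t = np.arange(20, dtype=float)
        np.testing.assert_allclose(compute_apg(t**2), 2.0)
        np.testing.assert_allclose(compute_apg(3 * t + 1), 0.0, atol=1e-12)

    def test_elementwise_oracles_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            y = rng.normal(size=rng.integers(3, 60))
            np.testing.assert_array_equal(compute_vpg(y), vpg_oracle(y))
            np.testing.assert_array_equal(compute_apg(y), apg_oracle(y))

    def test_apg_is_vpg_of_vpg(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=50)
        np.testing.assert_array_equal(compute_apg(y), compute_vpg(compute_vpg(y)))

    def test_physical_units_scaling(self):
        y = np.array([0.0, 1.0, 3.0, 6.0])
        np.testing.assert_allclose(compute_vpg(y, 127.0), np.diff(y) * 127.0)
        np.testing.assert_allclose(compute_apg(y, 127.0), np.diff(y, 2) * 127.0**2)

    @pytest.mark.parametrize("func, n", [(compute_vpg, 1), (compute_apg, 2)])
    def test_too_short_rejected(self, func, n):
        with pytest.raises(ValueError):
            func(np.ones(n))

    def test_lengths(self):
        y = np.zeros(100)
        d = DerivativeSet.from_signal(y, 127.0)
        assert d.vpg.size == 99 and d.apg.size == 98


class TestApgWaves:
    def test_clean_pulse_full_pattern_and_notch_alignment(self, clean_cohort):
        records, _ = clean_cohort
        for rec in records[:6]:
            filt, selected, morph, _ = prepare_pulses(rec)
            for seg in selected:
                mp = morph[seg.start_index : seg.end_index]
                fid = detect_apg_waves(seg, DerivativeSet.from_signal(mp, rec.fs_hz))
                assert fid.a[1] > 0 and fid.b[1] < 0
                assert fid.has_cd
                assert fid.a[0] < fid.b[0] < fid.c[0] < fid.d[0] < fid.e[0]
                notches = [
                    n - seg.start_index
                    for n in rec.ground_truth.notches
                    if seg.start_index <= n < seg.end_index
                ]
                assert notches and abs(fid.e[0] - notches[0]) <= 3

    def test_amplitude_scaling_preserves_indices(self, clean_record_72bpm):
        filt, selected, morph, _ = prepare_pulses(clean_record_72bpm)
        seg = selected[0]
        mp = morph[seg.start_index : seg.end_index]
        f1 = detect_apg_waves(seg, DerivativeSet.from_signal(mp, 127.0))
        f2 = detect_apg_waves(seg, DerivativeSet.from_signal(mp * 3.0, 127.0))
        for wave in "abcde":
            w1, w2 = getattr(f1, wave), getattr(f2, wave)
            assert w1[0] == w2[0]
            assert w2[1] == pytest.approx(3.0 * w1[1])

    def test_vanishing_notch_flags_cd_absent(self):
        cfg = SynthConfig(
            n_subjects=2,
            noise=NoiseConfig.silent(),
            subject_jitter_sd={},
            glucose_effect_sizes={},
            morphology=MorphologyParams(notch_depth_fraction=0.0),
            seed=5,
        )
        records, _ = generate_cohort(cfg)
        for rec in records:
            _, selected, morph, _ = prepare_pulses(rec)
            for seg in selected:
                mp = morph[seg.start_index : seg.end_index]
                fid = detect_apg_waves(seg, DerivativeSet.from_signal(mp, rec.fs_hz))
                assert not fid.has_cd
                assert fid.a[0] < fid.b[0] < fid.e[0]

    def test_ordering_violation_rejected(self):
        with pytest.raises(FiducialError):
            FiducialSet(a=(10, 1.0), b=(5, -1.0), e=(20, 0.5))


class TestApgRatios:
    def test_direct_arithmetic(self):
        f = FiducialSet(a=(1, 1.0), b=(2, -0.5), c=(3, 0.0), d=(4, 0.0), e=(5, 0.2))
        r = apg_ratios(f)
        assert r["b_over_a"] == pytest.approx(-0.5)
        assert r["b_minus_e_over_a"] == pytest.approx(-0.7)
        assert r["c_plus_d_minus_b_over_a"] == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            amps = rng.normal(size=5)
            amps[0] = abs(amps[0]) + 0.1
            f1 = FiducialSet(
                a=(1, amps[0]), b=(2, amps[1]), c=(3, amps[2]), d=(4, amps[3]), e=(5, amps[4])
            )
            c = float(rng.uniform(0.1, 10))
            f2 = FiducialSet(
                a=(1, c * amps[0]), b=(2, c * amps[1]), c=(3, c * amps[2]), d=(4, c * amps[3]), e=(5, c * amps[4])
            )
            r1, r2 = apg_ratios(f1), apg_ratios(f2)
            for k in RATIO_COLUMNS:
                assert r1[k] == pytest.approx(r2[k], rel=1e-9)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d, e = rng.normal(size=5)
            a = abs(a) + 0.1
            f = FiducialSet(a=(1, a), b=(2, b), c=(3, c), d=(4, d), e=(5, e))
            r = apg_ratios(f)
            oracle = {
                "b_over_a": b / a,
                "c_over_a": c / a,
                "d_over_a": d / a,
                "e_over_a": e / a,
                "b_minus_c_minus_d_minus_e_over_a": (b - c - d - e) / a,
                "b_minus_e_over_a": (b - e) / a,
                "b_minus_c_minus_d_over_a": (b - c - d) / a,
                "c_plus_d_minus_b_over_a": (c + d - b) / a,
            }
            for k, v in oracle.items():
                assert abs(r[k] - v) < 1e-12

    def test_absent_cd_propagates(self):
        r = apg_ratios(FiducialSet(a=(1, 1.0), b=(2, -0.5), e=(5, 0.2)))
        assert np.isnan(r["c_over_a"]) and np.isnan(r["c_plus_d_minus_b_over_a"])
        assert r["b_over_a"] == pytest.approx(-0.5)

    def test_zero_a_rejected(self):
        with pytest.raises(FiducialError):
            apg_ratios(FiducialSet(a=(1, 0.0), b=(2, -0.5), e=(5, 0.2)))


class TestStatisticalFeatures:
    def test_constant_series(self):
        s = statistical_features([1.0, 1.0, 1.0, 1.0])
        assert s["min"] == s["max"] == s["mean"] == s["rms"] == 1.0
        assert s["sd"] == s["var"] == 0.0
        assert s["s_energy"] == 4.0

    def test_hand_arithmetic_sample_convention(self):
        s = statistical_features([1.0, 2.0, 3.0])
        assert s["mean"] == 2.0
        assert s["var"] == pytest.approx(1.0)  # (n-1) convention
        assert s["sd"] == pytest.approx(1.0)
        assert s["s_energy"] == pytest.approx(14.0)
        assert s["rms"] == pytest.approx(np.sqrt(14.0 / 3.0))

    def test_negation_symmetry(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=64)
        s1, s2 = statistical_features(y), statistical_features(-y)
        assert s1["min"] == -s2["max"] and s1["max"] == -s2["min"]
        for k in ("sd", "var", "rms", "s_energy"):
            assert s1[k] == pytest.approx(s2[k])

    def test_var_is_sd_squared(self, feature_table):
        for sig in ("ppg", "vpg", "apg"):
            np.testing.assert_allclose(
                feature_table[f"{sig}_var"], feature_table[f"{sig}_sd"] ** 2, rtol=1e-9
            )


class TestWaveformFeatures:
    def test_60bpm_intervals_are_one_second(self, clean_record_60bpm):
        rec = clean_record_60bpm
        filt, selected, morph, peaks = prepare_pulses(rec)
        row = assemble_feature_vector(filt, selected, morph, peaks)
        assert row["p_pint"] == pytest.approx(1.0, abs=0.02)
        assert row["pulse_width"] == pytest.approx(1.0, abs=0.02)
        assert row["t_interval"] == pytest.approx(1.0, abs=0.02)
        assert row["p_rate"] == pytest.approx(60.0, abs=1.0)

    def test_planted_systolic_to_diastolic_ratio(self):
        cfg = SynthConfig(
            n_subjects=2,
            noise=NoiseConfig.silent(),
            subject_jitter_sd={},
            glucose_effect_sizes={},
            morphology=MorphologyParams(systolic_amplitude=1.0, diastolic_amplitude_fraction=0.4),
            seed=5,
        )
        records, _ = generate_cohort(cfg)
        for rec in records:
            filt, selected, morph, peaks = prepare_pulses(rec)
            row = assemble_feature_vector(filt, selected, morph, peaks)
            assert row["s_peak"] / row["d_peak"] == pytest.approx(2.5, rel=0.10)

    def test_three_peak_average(self, clean_record_72bpm):
        filt, selected, morph, peaks = prepare_pulses(clean_record_72bpm)
        morph_pulses = [morph[s.start_index : s.end_index] for s in selected]
        fiducials = [
            detect_apg_waves(s, DerivativeSet.from_signal(mp, 127.0))
            for s, mp in zip(selected, morph_pulses)
        ]
        wf = waveform_features(selected, morph_pulses, fiducials, 127.0, peaks)
        per_pulse = [float(np.max(mp) - np.min(mp)) for mp in morph_pulses]
        assert wf.s_peak == pytest.approx(np.mean(per_pulse))


class TestFeatureVector:
    def test_canonical_columns(self, feature_table):
        assert list(feature_table.columns) == list(FEATURE_COLUMNS) + list(METADATA_COLUMNS)
        assert len(FEATURE_COLUMNS) == 35

    def test_pipeline_determinism(self, clean_record_72bpm):
        ext = WaveformFeatureExtractor()
        t1 = ext.fit([clean_record_72bpm]).transform([clean_record_72bpm])
        t2 = ext.transform([clean_record_72bpm])
        assert t1.equals(t2)

    def test_amplitude_scaling_contract(self, clean_record_72bpm):
        rec = clean_record_72bpm
        doubled = rec.replace(samples=rec.samples * 2.0)
        ext = WaveformFeatureExtractor()
        r1 = ext.fit([rec]).transform([rec]).iloc[0]
        r2 = ext.transform([doubled]).iloc[0]
        for col in RATIO_COLUMNS:
            assert r2[col] == pytest.approx(r1[col], rel=1e-6)
        for col in ("ppg_min", "ppg_max", "s_peak", "d_peak"):
            assert r2[col] == pytest.approx(2.0 * r1[col], rel=1e-6)
        assert r2["ppg_s_energy"] == pytest.approx(4.0 * r1["ppg_s_energy"], rel=1e-6)

    def test_noise_free_cohort_yields_complete_vectors(self, clean_cohort):
        records, _ = clean_cohort
        table = WaveformFeatureExtractor().fit(records).transform(records)
        assert len(table) == len(records)
        assert int(table[list(FEATURE_COLUMNS)].isna().sum().sum()) == 0

    def test_failure_names_the_record(self):
        from conftest import make_record

        flat = make_record(np.zeros(1905), subject_id="S099", state="fasting")
        with pytest.raises(ValueError, match="S099"):
            WaveformFeatureExtractor().fit([flat]).transform([flat])

    def test_per_pulse_stats_mode(self, clean_record_72bpm):
        rec = clean_record_72bpm
        t = WaveformFeatureExtractor(per_pulse_stats=True).fit([rec]).transform([rec])
        assert list(t.columns) == list(FEATURE_COLUMNS) + list(METADATA_COLUMNS)
        assert t.notna().all().all()
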