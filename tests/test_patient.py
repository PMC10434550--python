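"""Nasal-pressure pipeline: normalization, conductance fit, integration,
and end-to-end recovery on synthetic recordings."""

import numpy as np
import pytest

from oxsa.breathing import BreathingSpec, EventAnnotation
from oxsa.errors import FitError, ParameterValidationError
from oxsa.patient import (
    NasalPressureRecord,
    PatientProfile,
    fit_nasal_conductance,
    generate_synthetic_record,
    ideal_body_weight,
    normalize_pressure,
    pressure_to_lung_volume,
)

FS = 25.0


def make_record(times, pressure, annotations=()):
    return NasalPressureRecord(
        times=times, pressure=pressure, sampling_rate=FS, annotations=annotations
    )


@pytest.fixture()
def profile():
    # overweight-range adult male; tidal volume from 7 mL/kg IBW
    return PatientProfile(height=1.78, weight=84.1)


@pytest.fixture()
def ideal_spec(profile):
    return BreathingSpec(
        V_T=profile.tidal_volume,
        V_D=profile.dead_space,
        V_End=profile.frc,
        b_r=12.0,
        total_duration=300.0,
        stabilization_time=0.0,
    )


class TestProfile:
    def test_bmi_classes_match_patient_table(self):
        # 26.6 kg/m^2 -> overweight FRC branch; 30.7 -> obese branch
        p1 = PatientProfile(height=1.78, weight=84.1)
        p2 = PatientProfile(height=1.85, weight=105.7)
        assert p1.bmi == pytest.approx(26.6, abs=0.25)
        assert p2.bmi == pytest.approx(30.7, abs=0.25)
        assert p1.bmi_class == "overweight" and p1.frc == 2.6
        assert p2.bmi_class == "obese" and p2.frc == 2.1

    def test_devine_ideal_body_weight(self):
        # 1.78 m male: 50 + 2.3 * (70.1 - 60) inches
        assert ideal_body_weight(1.78, "M") == pytest.approx(73.2, abs=0.2)
        assert ideal_body_weight(1.78, "F") == pytest.approx(68.7, abs=0.2)


class TestNormalizePressure:
    def test_constant_signal_zeroed(self):
        t = np.arange(0, 100, 1 / FS)
        rec = make_record(t, np.full(t.size, 3.7))
        assert normalize_pressure(rec, 30.0) == pytest.approx(0.0)

    def test_fast_sinusoid_preserved(self):
        # oscillation with period << window passes the high-pass unchanged
        t = np.arange(0, 200, 1 / FS)
        sig = np.sin(2 * np.pi * t / 4.0)
        rec = make_record(t, sig)
        out = normalize_pressure(rec, 60.0)
        core = slice(int(40 * FS), int(160 * FS))
        assert np.max(np.abs(out[core] - sig[core])) < 0.01

    def test_linear_drift_removed(self):
        t = np.arange(0, 200, 1 / FS)
        sig = np.sin(2 * np.pi * t / 4.0)
        rec = make_record(t, sig + 0.05 * t)
        out = normalize_pressure(rec, 40.0)
        core = slice(int(40 * FS), int(160 * FS))
        assert np.max(np.abs(out[core] - sig[core])) < 0.02

    def test_window_longer_than_record_rejected(self):
        t = np.arange(0, 10, 1 / FS)
        rec = make_record(t, np.zeros(t.size))
        with pytest.raises(ParameterValidationError, match="window"):
            normalize_pressure(rec, 60.0)


class TestConductanceFit:
    def test_recovers_known_conductance(self, profile, ideal_spec):
        g_true = 0.04
        rec = generate_synthetic_record(
            ideal_spec, g_true, noise_sd=0.02, drift_amplitude=0.1, seed=7
        )
        fitted = fit_nasal_conductance(rec, profile, (30.0, 120.0))
        assert fitted.conductance == pytest.approx(g_true, rel=0.05)
        assert fitted.breathing_rate == pytest.approx(12.0, rel=0.02)

    def test_scale_equivariance(self, profile, ideal_spec):
        rec = generate_synthetic_record(
            ideal_spec, 0.04, noise_sd=0.0, drift_amplitude=0.0, seed=0
        )
        doubled = make_record(rec.times, 2.0 * rec.pressure)
        g1 = fit_nasal_conductance(rec, profile, (30.0, 120.0)).conductance
        g2 = fit_nasal_conductance(doubled, profile, (30.0, 120.0)).conductance
        assert g2 == pytest.approx(g1 / 2.0, rel=1e-6)

    def test_too_few_breaths_is_fit_error(self, profile, ideal_spec):
        rec = generate_synthetic_record(ideal_spec, 0.04, seed=0)
        with pytest.raises(FitError, match="breaths"):
            fit_nasal_conductance(rec, profile, (30.0, 36.0))


class TestPressureToLungVolume:
    def test_zero_pressure_gives_flat_volume_at_anchor(self, profile):
        t = np.arange(0, 120, 1 / FS)
        rec = make_record(t, np.zeros(t.size))
        prof = PatientProfile(height=1.78, weight=84.1, conductance=0.05)
        pat = pressure_to_lung_volume(rec, prof)
        assert np.ptp(pat.V_A) == pytest.approx(0.0, abs=1e-9)

    def test_requires_fitted_conductance(self, profile):
        t = np.arange(0, 120, 1 / FS)
        rec = make_record(t, np.zeros(t.size))
        with pytest.raises(FitError, match="conductance"):
            pressure_to_lung_volume(rec, profile)

    def test_volume_recovered_from_clean_pressure(self, profile, ideal_spec):
        from oxsa.breathing import build_pattern

        g = 0.04
        rec = generate_synthetic_record(
            ideal_spec, g, noise_sd=0.0, drift_amplitude=0.0, seed=0
        )
        prof = fit_nasal_conductance(rec, profile, (30.0, 120.0))
        pat = pressure_to_lung_volume(rec, prof)
        truth = build_pattern(ideal_spec, 1 / FS, include_stabilization=False)
        core = slice(int(40 * FS), int(260 * FS))
        rms = np.sqrt(np.mean((pat.V_A[core] - truth.V_A[core]) ** 2))
        assert rms / np.mean(truth.V_A[core]) < 0.02

    def test_apnea_epoch_gives_flat_volume(self, profile):
        spec = BreathingSpec(
            V_T=profile.tidal_volume,
            V_D=profile.dead_space,
            V_End=profile.frc,
            b_r=12.0,
            events=(EventAnnotation("apnea", 100.0, 20.0),),
            total_duration=300.0,
            stabilization_time=0.0,
        )
        rec = generate_synthetic_record(spec, 0.04, noise_sd=0.0,
                                        drift_amplitude=0.0, seed=0)
        prof = fit_nasal_conductance(rec, profile, (30.0, 90.0))
        pat = pressure_to_lung_volume(rec, prof)
        mask = (rec.times >= 103.0) & (rec.times <= 117.0)
        assert np.ptp(pat.V_A[mask]) < 0.02


class TestSyntheticGenerator:
    def test_noise_free_pressure_proportional_to_flow(self, ideal_spec):
        from oxsa.breathing import build_pattern

        g = 0.05
        rec = generate_synthetic_record(
            ideal_spec, g, noise_sd=0.0, drift_amplitude=0.0, seed=1
        )
        truth = build_pattern(ideal_spec, 1 / FS, include_stabilization=False)
        assert rec.pressure == pytest.approx(truth.dV_A_dt / g, abs=1e-12)

    def test_reproducible_for_fixed_seed(self, ideal_spec):
        a = generate_synthetic_record(ideal_spec, 0.04, seed=42)
        b = generate_synthetic_record(ideal_spec, 0.04, seed=42)
        assert a.pressure == pytest.approx(b.pressure, abs=0.0)

    def test_annotated_apneas_align_with_zero_flow(self, profile):
        spec = BreathingSpec(
            V_T=0.5, V_D=0.15, V_End=2.3, b_r=12.0,
            events=(EventAnnotation("apnea", 50.0, 20.0),),
            total_duration=200.0, stabilization_time=0.0,
        )
        rec = generate_synthetic_record(spec, 0.04, noise_sd=0.0,
                                        drift_amplitude=0.0, seed=0)
        assert len(rec.annotations) == 1
        ev = rec.annotations[0]
        mask = (rec.times >= ev.start) & (rec.times < ev.end)
        assert np.max(np.abs(rec.pressure[mask])) == pytest.approx(0.0, abs=1e-12)
        outside = np.max(np.abs(rec.pressure)) > 0.1
        assert outside


class TestEndToEnd:
    def test_volume_recovered_within_3pct_rms_at_default_noise(
        self, profile, ideal_spec
    ):
        from oxsa.breathing import build_pattern

        g = 0.04
        rec = generate_synthetic_record(ideal_spec, g, seed=11)  # default noise
        prof = fit_nasal_conductance(rec, profile, (30.0, 120.0))
        pat = pressure_to_lung_volume(rec, prof)
        truth = build_pattern(ideal_spec, 1 / FS, include_stabilization=False)
        core = slice(int(40 * FS), int(260 * FS))
        rms = np.sqrt(np.mean((pat.V_A[core] - truth.V_A[core]) ** 2))
        assert rms / np.mean(truth.V_A[core]) < 0.03

    def test_annotations_survive_pipeline(self, profile):
        spec = BreathingSpec(
            V_T=profile.tidal_volume, V_D=profile.dead_space, V_End=profile.frc,
            b_r=12.0,
            events=(EventAnnotation("apnea", 150.0, 15.0),),
            total_duration=300.0, stabilization_time=0.0,
        )
        rec = generate_synthetic_record(spec, 0.04, seed=3)
        prof = fit_nasal_conductance(rec, profile, (30.0, 120.0))
        pat = pressure_to_lung_volume(rec, prof)
        assert pat.events == rec.annotations
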