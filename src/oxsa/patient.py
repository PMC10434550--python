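"""Nasal-pressure signal processing: recorded pressure -> model lung volume.

For a laminar flow-pressure relationship, nasal flow is proportional to
the recorded nasal pressure.  The pipeline is:

1. normalize the raw pressure to zero mean by subtracting a centered
   moving average (removes baseline wander and sensor offset);
2. fit the patient's total nasal conductance on a clinician-identified
   normal-breathing segment, by equating the mean per-breath maximum
   pressure with the peak inspiratory flow of an ideal sinusoidal
   breathing pattern built from the patient's ideal-body-weight tidal
   volume and a BMI-class functional residual capacity;
3. scale pressure to flow and integrate over time to a lung-volume trace,
   re-anchoring its slow baseline so the integrated signal oscillates
   about the ideal mid-tidal volume (controls integrator drift);
4. use the volume trace directly as the alveolar-volume model input.

A synthetic nasal-pressure generator (the exact inverse of this pipeline
plus baseline drift and additive Gaussian noise) provides reproducible
stand-ins for clinical recordings and supports end-to-end parameter
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import find_peaks

from .breathing import BreathingPattern, BreathingSpec, EventAnnotation, build_pattern
from .errors import DataError, FitError, ParameterValidationError

#: Default functional residual capacity (L) by BMI class; published
#: averages for subjects suspected of OSA are configuration, not constants.
FRC_BY_BMI_CLASS = {"normal": 3.0, "overweight": 2.6, "obese": 2.1}

#: Tidal volume per kg of ideal body weight (L/kg).
TIDAL_VOLUME_PER_KG_IBW = 0.007


@dataclass(frozen=True)
class NasalPressureRecord:
    """Uniformly sampled nasal pressure with event annotations."""

    times: np.ndarray  # s
    pressure: np.ndarray  # arbitrary recorder units
    sampling_rate: float  # Hz
    annotations: tuple[EventAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, float)
        pressure = np.asarray(self.pressure, float)
        if times.shape != pressure.shape:
            raise ParameterValidationError("times and pressure must align")
        if times.size >= 2:
            dts = np.diff(times)
            if np.max(np.abs(dts - dts[0])) > 1e-6 * dts[0]:
                raise ParameterValidationError("sampling must be uniform")
        if not np.all(np.isfinite(pressure)):
            raise DataError("pressure contains non-finite samples")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pressure", pressure)
        object.__setattr__(self, "annotations", tuple(self.annotations))


def ideal_body_weight(height_m: float, sex: str = "M") -> float:
    """Devine-formula ideal body weight, kg."""
    inches = height_m / 0.0254
    base = 50.0 if sex.upper().startswith("M") else 45.5
    return base + 2.3 * (inches - 60.0)


@dataclass(frozen=True)
class PatientProfile:
    """Anthropometrics plus the fitted signal-conversion parameters."""

    height: float  # m
    weight: float  # kg
    sex: str = "M"
    dead_space: float = 0.15  # L
    frc_by_class: dict = field(default_factory=lambda: dict(FRC_BY_BMI_CLASS))
    tidal_volume_override: float | None = None
    conductance: float | None = None  # L/s per recorder unit, fitted
    breathing_rate: float | None = None  # breaths/min, estimated

    def __post_init__(self) -> None:
        if self.height <= 0 or self.weight <= 0:
            raise ParameterValidationError("height and weight must be positive")
        if self.conductance is not None and self.conductance <= 0:
            raise ParameterValidationError("conductance must be positive")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2

    @property
    def bmi_class(self) -> str:
        if self.bmi >= 30.0:
            return "obese"
        if self.bmi >= 25.0:
            return "overweight"
        return "normal"

    @property
    def frc(self) -> float:
        """End-expiration (functional residual) volume for the BMI class, L."""
        return self.frc_by_class[self.bmi_class]

    @property
    def tidal_volume(self) -> float:
        """Ideal-body-weight tidal volume (7 mL/kg IBW), L."""
        if self.tidal_volume_override is not None:
            return self.tidal_volume_override
        return TIDAL_VOLUME_PER_KG_IBW * ideal_body_weight(self.height, self.sex)


def normalize_pressure(record: NasalPressureRecord, window: float) -> np.ndarray:
    """Zero-mean pressure: raw minus a centered moving average of ``window``
    seconds; edge windows shrink rather than pad."""
    if window <= 0:
        raise ParameterValidationError("window must be positive")
    n_samples = int(round(window * record.sampling_rate))
    if n_samples > record.times.size:
        raise ParameterValidationError(
            f"window ({window} s) longer than the record "
            f"({record.times.size / record.sampling_rate:.1f} s)"
        )
    ma = (
        pd.Series(record.pressure)
        .rolling(n_samples, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return record.pressure - ma


def _ideal_peak_flow(v_vent: float, b_r: float) -> float:
    """Peak inspiratory flow of the sinusoidal pattern, L/s."""
    return np.pi * v_vent * b_r / 60.0


def fit_nasal_conductance(
    record: NasalPressureRecord,
    profile: PatientProfile,
    normal_segment: tuple[float, float],
    *,
    window: float = 60.0,
    min_breaths: int = 3,
) -> PatientProfile:
    """Fit the total nasal conductance on a normal-breathing segment.

    The breathing rate is estimated from the inspiratory peaks of the
    normalized pressure in the segment; the conductance is the ratio of
    the ideal pattern's peak inspiratory flow to the mean per-breath
    maximum pressure (laminar, linear flow-pressure relation).
    """
    p_norm = normalize_pressure(record, window)
    lo, hi = normal_segment
    mask = (record.times >= lo) & (record.times <= hi)
    if not np.any(mask):
        raise FitError("normal segment contains no samples")
    seg_t = record.times[mask]
    seg_p = p_norm[mask]
    spread = float(np.std(seg_p))
    if spread == 0.0:
        raise FitError("normal segment is flat; cannot detect breaths")
    peaks, _ = find_peaks(
        seg_p,
        height=0.5 * spread,
        distance=max(1, int(record.sampling_rate * 1.0)),
    )
    if peaks.size < min_breaths:
        raise FitError(
            f"detected only {peaks.size} breaths in the normal segment; "
            f"need at least {min_breaths}"
        )
    b_r = 60.0 * (peaks.size - 1) / (seg_t[peaks[-1]] - seg_t[peaks[0]])
    mean_peak = float(np.mean(seg_p[peaks]))
    if mean_peak <= 0:
        raise DataError("mean per-breath maximum pressure is not positive")
    v_vent = profile.tidal_volume - profile.dead_space
    if v_vent <= 0:
        raise ParameterValidationError("tidal volume must exceed dead space")
    conductance = _ideal_peak_flow(v_vent, b_r) / mean_peak
    return replace(profile, conductance=conductance, breathing_rate=b_r)


def pressure_to_lung_volume(
    record: NasalPressureRecord,
    profile: PatientProfile,
    *,
    window: float = 60.0,
) -> BreathingPattern:
    """Convert nasal pressure to a model-ready alveolar-volume trace.

    flow = conductance * normalized pressure; volume = cumulative
    trapezoid integral of flow.  The slow baseline of the integrated
    trace (moving average over the same window) is re-anchored to the
    ideal mid-tidal volume FRC + V_vent/2 to control integrator drift.
    During apneas this anchor biases the baseline by up to half a tidal
    volume; see the package methods notes.
    """
    if profile.conductance is None:
        raise FitError("conductance has not been fitted; run fit_nasal_conductance")
    p_norm = normalize_pressure(record, window)
    flow = profile.conductance * p_norm
    vol = cumulative_trapezoid(flow, record.times, initial=0.0)
    n_samples = int(round(window * record.sampling_rate))
    baseline = (
        pd.Series(vol).rolling(n_samples, center=True, min_periods=1).mean().to_numpy()
    )
    anchor = profile.frc + 0.5 * (profile.tidal_volume - profile.dead_space)
    v_a = vol - baseline + anchor
    if np.any(v_a < 0):
        raise DataError(
            "integrated lung volume went negative; review the drift "
            "correction window and the fitted conductance"
        )
    dv = np.gradient(v_a, record.times)
    return BreathingPattern(
        times=record.times, V_A=v_a, dV_A_dt=dv, events=record.annotations
    )


def generate_synthetic_record(
    spec: BreathingSpec,
    conductance: float,
    *,
    sampling_rate: float = 25.0,
    noise_sd: float = 0.02,
    drift_amplitude: float = 0.1,
    seed: int | None = None,
    include_stabilization: bool = False,
) -> NasalPressureRecord:
    """Synthetic nasal-pressure recording for a simulated breathing spec.

    The alveolar-volume trace of ``spec`` is differentiated to flow and
    divided by ``conductance`` to pressure; slow sinusoidal baseline
    drift (``drift_amplitude``, recorder units, ~minute-scale periods)
    and white Gaussian noise (``noise_sd``, recorder units) emulate
    recording artifacts.  Annotations pass through unchanged.
    Deterministic for a fixed ``seed``.
    """
    if conductance <= 0:
        raise ParameterValidationError("conductance must be positive")
    rng = np.random.default_rng(seed)
    pattern = build_pattern(
        spec, 1.0 / sampling_rate, include_stabilization=include_stabilization
    )
    t = pattern.times
    pressure = pattern.dV_A_dt / conductance
    if drift_amplitude > 0:
        phases = rng.uniform(0, 2 * np.pi, size=2)
        drift = drift_amplitude * (
            np.sin(2 * np.pi * t / 97.0 + phases[0])
            + 0.5 * np.sin(2 * np.pi * t / 211.0 + phases[1])
        )
        pressure = pressure + drift
    if noise_sd > 0:
        pressure = pressure + rng.normal(0.0, noise_sd, size=t.size)
    return NasalPressureRecord(
        times=t,
        pressure=pressure,
        sampling_rate=sampling_rate,
        annotations=pattern.events,
    )
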