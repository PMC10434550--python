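"""Simulated alveolar-volume breathing patterns and the apnea-hypopnea index.

Normal tidal breathing is approximated by a sinusoid in alveolar volume,

    V_A(t) = 1/2 V_vent sin(2 pi b_r t - pi/2) + 1/2 V_vent + V_End,
    V_vent = V_T - V_D,

which starts each breath at end-expiration (V_A = V_End) and assumes equal
inspiration and expiration durations.  Obstructive-event patterns are
built piecewise from this template: during an apnea the trace is held flat
at V_End, during a hypopnea the oscillation amplitude is scaled by the
remaining airflow fraction, and during hyperventilation the tidal volume
and breathing rate are overridden.  After every event the sinusoid
restarts at end-expiration phase so the trace stays continuous at V_End;
events should therefore begin on breath boundaries (the bundled scenarios
do), otherwise a small discontinuity is flagged with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterValidationError

#: Event kinds that modify the alveolar-volume trace.
RESPIRATORY_KINDS = ("apnea", "hypopnea", "hyperventilation")
#: Annotation-only kinds (scoring / staging); any other string is treated
#: as a sleep-stage label and also left out of the trace construction.
ANNOTATION_KINDS = ("RERA", "wake", "sleep")

#: Default minimum duration (s) for an apnea/hypopnea to be scored.
MIN_SCORED_EVENT_DURATION_S = 10.0


@dataclass(frozen=True)
class EventAnnotation:
    """A typed, timestamped interval within a breathing record."""

    kind: str
    start: float
    duration: float
    airflow_fraction: float = 0.0
    override_V_T: float | None = None
    override_b_r: float | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterValidationError("event duration must be > 0")
        if not 0.0 <= self.airflow_fraction <= 1.0:
            raise ParameterValidationError("airflow_fraction must lie in [0, 1]")
        if self.kind == "apnea" and self.airflow_fraction != 0.0:
            raise ParameterValidationError("an apnea has zero airflow by definition")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def is_respiratory(self) -> bool:
        return self.kind in ("apnea", "hypopnea")

    @property
    def shapes_trace(self) -> bool:
        return self.kind in RESPIRATORY_KINDS


@dataclass(frozen=True)
class BreathingSpec:
    """Parameters of a simulated breathing pattern.

    Volumes in L, breathing rate in breaths/min, times in s.
    """

    V_T: float = 0.5
    V_D: float = 0.15
    V_End: float = 2.3
    b_r: float = 12.0
    events: tuple[EventAnnotation, ...] = field(default_factory=tuple)
    total_duration: float = 600.0
    stabilization_time: float = 360.0

    def __post_init__(self) -> None:
        if not self.V_T > self.V_D > 0:
            raise ParameterValidationError(
                f"need V_T > V_D > 0, got V_T={self.V_T}, V_D={self.V_D}"
            )
        if self.V_End <= 0 or self.b_r <= 0 or self.total_duration <= 0:
            raise ParameterValidationError(
                "V_End, b_r and total_duration must be positive"
            )
        object.__setattr__(self, "events", tuple(self.events))
        shaping = sorted(
            (e for e in self.events if e.shapes_trace), key=lambda e: e.start
        )
        for ev in shaping:
            if ev.start < 0 or ev.end > self.total_duration + 1e-9:
                raise ParameterValidationError(
                    f"event {ev.kind} at t={ev.start}s extends outside "
                    f"[0, {self.total_duration}] s"
                )
        for a, b in zip(shaping, shaping[1:]):
            if b.start < a.end - 1e-9:
                raise ParameterValidationError(
                    f"overlapping events at t={a.start}s and t={b.start}s"
                )

    @property
    def V_vent(self) -> float:
        """Alveolar ventilation volume per breath, V_T - V_D (L)."""
        return self.V_T - self.V_D


@dataclass(frozen=True)
class BreathingPattern:
    """Sampled alveolar-volume trace with its derivative and annotations."""

    times: np.ndarray
    V_A: np.ndarray
    dV_A_dt: np.ndarray
    events: tuple[EventAnnotation, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        V_A = np.asarray(self.V_A, dtype=float)
        dV = np.asarray(self.dV_A_dt, dtype=float)
        if not (times.shape == V_A.shape == dV.shape):
            raise ParameterValidationError("times, V_A, dV_A_dt must align")
        if np.any(V_A < 0):
            raise ParameterValidationError("alveolar volume must be non-negative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "V_A", V_A)
        object.__setattr__(self, "dV_A_dt", dV)
        object.__setattr__(self, "events", tuple(self.events))


def _sinusoid(t_local, amplitude, rate_bpm, V_End):
    """Eq-7-style segment; t_local is time since segment start (s)."""
    f = rate_bpm / 60.0
    phase = 2.0 * np.pi * f * t_local - 0.5 * np.pi
    V = 0.5 * amplitude * np.sin(phase) + 0.5 * amplitude + V_End
    dV = np.pi * amplitude * f * np.cos(phase)
    return V, dV


def normal_pattern(spec: BreathingSpec, times: np.ndarray) -> BreathingPattern:
    """Sinusoidal normal breathing on the given time grid."""
    times = np.asarray(times, dtype=float)
    V, dV = _sinusoid(times - times[0], spec.V_vent, spec.b_r, spec.V_End)
    return BreathingPattern(times=times, V_A=V, dV_A_dt=dV, events=())


def _segments(spec: BreathingSpec):
    """Piecewise description of the trace: (t0, t1, amplitude, rate)."""
    shaping = sorted(
        (e for e in spec.events if e.shapes_trace), key=lambda e: e.start
    )
    segs = []
    cursor = 0.0
    for ev in shaping:
        if ev.start > cursor:
            segs.append((cursor, ev.start, spec.V_vent, spec.b_r))
        if ev.kind == "apnea":
            segs.append((ev.start, ev.end, 0.0, spec.b_r))
        elif ev.kind == "hypopnea":
            segs.append((ev.start, ev.end, ev.airflow_fraction * spec.V_vent, spec.b_r))
        else:  # hyperventilation
            v_t = ev.override_V_T if ev.override_V_T is not None else spec.V_T
            b_r = ev.override_b_r if ev.override_b_r is not None else spec.b_r
            if v_t <= spec.V_D:
                raise ParameterValidationError(
                    "hyperventilation override_V_T must exceed dead space"
                )
            segs.append((ev.start, ev.end, v_t - spec.V_D, b_r))
        cursor = ev.end
    if cursor < spec.total_duration:
        segs.append((cursor, spec.total_duration, spec.V_vent, spec.b_r))
    return segs


def pattern_with_events(spec: BreathingSpec, times: np.ndarray) -> BreathingPattern:
    """Breathing pattern with apnea/hypopnea/hyperventilation events.

    Each segment restarts the sinusoid at end-expiration phase; a warning
    is issued if a segment boundary does not fall at end-expiration (i.e.
    the preceding segment was cut mid-breath).
    """
    times = np.asarray(times, dtype=float)
    t0 = times[0]
    V = np.empty_like(times)
    dV = np.empty_like(times)
    for seg_start, seg_end, amplitude, rate in _segments(spec):
        lo, hi = seg_start + t0, seg_end + t0
        mask = (times >= lo - 1e-12) & (times < hi - 1e-12)
        if seg_end >= spec.total_duration:  # include the final sample
            mask |= times >= hi - 1e-12
        V[mask], dV[mask] = _sinusoid(times[mask] - lo, amplitude, rate, spec.V_End)
        # continuity check: does this segment end back at end-expiration?
        n_breaths = (seg_end - seg_start) * rate / 60.0
        if amplitude > 0 and abs(n_breaths - round(n_breaths)) > 1e-6:
            warnings.warn(
                f"segment [{seg_start}, {seg_end}] s cuts a breath "
                "mid-cycle; the trace will jump at the boundary",
                stacklevel=2,
            )
    return BreathingPattern(times=times, V_A=V, dV_A_dt=dV, events=spec.events)


def build_pattern(
    spec: BreathingSpec, dt: float, include_stabilization: bool = True
) -> BreathingPattern:
    """Sample the scenario on a uniform grid, optionally preceded by a
    normal-breathing stabilization period.

    With stabilization, events are shifted by ``spec.stabilization_time``
    so that the scenario proper starts once the model has settled.
    """
    if include_stabilization and spec.stabilization_time > 0:
        shift = spec.stabilization_time
        spec = replace(
            spec,
            events=tuple(replace(e, start=e.start + shift) for e in spec.events),
            total_duration=spec.total_duration + shift,
        )
    n = int(round(spec.total_duration / dt)) + 1
    times = np.arange(n) * dt
    return pattern_with_events(spec, times)


def compute_ahi(
    events,
    analyzed_time: float,
    *,
    min_duration: float = MIN_SCORED_EVENT_DURATION_S,
    apply_duration_filter: bool = True,
) -> float:
    """Apnea-hypopnea index: scored events per hour of analyzed breathing.

    Only apnea and hypopnea annotations count; with the duration filter on
    (clinical scoring), events shorter than ``min_duration`` seconds are
    excluded.  Any desaturation criterion for hypopneas is applied by the
    caller before scoring (it requires a simulation result).
    """
    if analyzed_time <= 0:
        raise ParameterValidationError("analyzed_time must be positive")
    count = 0
    for ev in events:
        if not ev.is_respiratory:
            continue
        if apply_duration_filter and ev.duration < min_duration:
            continue
        count += 1
    return count / (analyzed_time / 3600.0)
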