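"""Coupled alveolar-capillary-systemic oxygen transport simulation.

The three sub-models are advanced with an explicit (forward Euler)
finite-difference scheme on a fixed step dt:

1. the alveolar partial pressure is updated using the capillary spatial
   average from the previous time level,
2. the pulmonary capillary parcel queue takes up oxygen from the alveoli
   and advects with the pulmonary blood flow (equal to cardiac output,
   series circulation without shunt),
3. the systemic capillary queue consumes oxygen at the basal metabolic
   rate; its outlet feeds the pulmonary arteries.

A simulation starts from uniform initial conditions at the resting
arterial operating point and runs a normal-breathing stabilization
period (default 360 s) before the scenario proper begins; summary
metrics compare the scenario against the stabilized normal cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import breathing as _breathing
from .alveolar import inspired_partial_pressure
from .breathing import (
    BreathingPattern,
    BreathingSpec,
    EventAnnotation,
    build_pattern,
    compute_ahi,
)
from .capillary import DEFAULT_N_SLICES, CapillaryProfile, advance_capillary
from .circulation import (
    DEFAULT_N_PARCELS,
    SystemicState,
    cardiac_output_from_heart_rate,
    systemic_transit,
)
from .errors import CFLError, ParameterValidationError, SimulationError
from .hemoglobin import dissolved_from_total_array, saturation_from_pressure
from .parameters import PhysiologyParams
from ._kernels import HAVE_NUMBA, simulate_loop

logger = logging.getLogger(__name__)

#: Resting arterial O2 partial pressure (mmHg) used for the uniform
#: initial condition; any initialization reaching the same cyclic steady
#: state is equivalent, this one merely shortens the transient.
INITIAL_P_O2 = 99.0

DEFAULT_HEART_RATE_BPM = 75.0


@dataclass(frozen=True)
class SolverOptions:
    """Numerical scheme configuration.

    ``dt`` explicit step (s); ``n_slices`` pulmonary capillary parcels;
    ``n_systemic_parcels`` systemic capillary parcels; ``snapshot_times``
    simulation times (s) at which to store capillary spatial profiles.
    """

    dt: float = 0.005
    n_slices: int = DEFAULT_N_SLICES
    n_systemic_parcels: int = DEFAULT_N_PARCELS
    snapshot_times: tuple[float, ...] = ()
    #: "auto" uses the compiled loop when numba is available (and no
    #: capillary snapshots are requested); "python" forces the reference
    #: pure-Python path; "compiled" requires the compiled path.
    loop: str = "auto"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterValidationError("dt must be positive")
        if self.n_slices < 1 or self.n_systemic_parcels < 1:
            raise ParameterValidationError("parcel counts must be >= 1")
        if self.loop not in ("auto", "python", "compiled"):
            raise ParameterValidationError("loop must be auto/python/compiled")


@dataclass(frozen=True)
class CompartmentTrace:
    """Time series of a blood compartment's O2 state."""

    C_d: np.ndarray
    C_T: np.ndarray
    S: np.ndarray
    P: np.ndarray


@dataclass(frozen=True)
class CapillarySnapshot:
    time: float
    z_m: np.ndarray
    P_mmHg: np.ndarray


@dataclass(frozen=True)
class EventMetrics:
    """Per-event desaturation summary (systemic arterial trace)."""

    event: EventAnnotation
    t_min_s: float
    min_S_sa: float
    min_C_sa_d: float
    saturation_decrease_pct: float
    reoxygenation_time_s: float
    overshoot: bool


@dataclass(frozen=True)
class SummaryMetrics:
    """Scenario-level severity metrics relative to the normal cycle."""

    normal_avg: dict[str, float]
    pct_decrease_saturation: dict[str, float]
    pct_decrease_dissolved: dict[str, float]
    pct_reduction_mass_transfer: float
    per_event: tuple[EventMetrics, ...]

    def to_dict(self) -> dict:
        return {
            "normal_avg": dict(self.normal_avg),
            "pct_decrease_saturation": dict(self.pct_decrease_saturation),
            "pct_decrease_dissolved": dict(self.pct_decrease_dissolved),
            "pct_reduction_mass_transfer": self.pct_reduction_mass_transfer,
            "per_event": [
                {
                    "kind": m.event.kind,
                    "start_s": m.event.start,
                    "duration_s": m.event.duration,
                    "t_min_s": m.t_min_s,
                    "min_S_sa": m.min_S_sa,
                    "min_C_sa_d_uM": m.min_C_sa_d * 1e6,
                    "saturation_decrease_pct": m.saturation_decrease_pct,
                    "reoxygenation_time_s": m.reoxygenation_time_s,
                    "overshoot": m.overshoot,
                }
                for m in self.per_event
            ],
        }


@dataclass(frozen=True)
class SimulationResult:
    """All compartment traces plus inputs, on the solver time grid."""

    times: np.ndarray
    V_A: np.ndarray
    P_A: np.ndarray
    compartments: dict[str, CompartmentTrace]  # keys pa, pv, sa, sv
    Q: np.ndarray
    uptake_rate: np.ndarray  # alveolar->capillary O2 flux, mol/s
    events: tuple[EventAnnotation, ...]
    scenario_start: float
    snapshots: tuple[CapillarySnapshot, ...]
    params: PhysiologyParams
    options: SolverOptions

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_dataframe(self) -> pd.DataFrame:
        sa, sv = self.compartments["sa"], self.compartments["sv"]
        pa, pv = self.compartments["pa"], self.compartments["pv"]
        return pd.DataFrame(
            {
                "time_s": self.times,
                "V_A_L": self.V_A,
                "P_A_mmHg": self.P_A,
                "S_sa": sa.S,
                "S_sv": sv.S,
                "C_sa_d_uM": sa.C_d * 1e6,
                "C_sv_d_uM": sv.C_d * 1e6,
                "C_pa_T_uM": pa.C_T * 1e6,
                "C_pv_T_uM": pv.C_T * 1e6,
                "P_pv_mmHg": pv.P,
                "Q_L_s": self.Q,
            }
        )


def _as_q_series(hr, times: np.ndarray, params: PhysiologyParams) -> np.ndarray:
    """Heart-rate input (scalar or (times, bpm) series) -> Q on the grid."""
    if np.isscalar(hr):
        q = cardiac_output_from_heart_rate(float(hr), params)
        return np.full(times.size, q)
    hr_t, hr_v = hr
    hr_on_grid = np.interp(times, np.asarray(hr_t, float), np.asarray(hr_v, float))
    return cardiac_output_from_heart_rate(hr_on_grid, params)


def run_simulation(
    pattern: BreathingPattern,
    params: PhysiologyParams | None = None,
    hr=DEFAULT_HEART_RATE_BPM,
    options: SolverOptions | None = None,
    scenario_start: float = 0.0,
) -> SimulationResult:
    """Run the coupled model over the span of ``pattern``.

    ``hr`` is a constant heart rate in beats/min or a ``(times, bpm)``
    series covering the same span.  ``scenario_start`` marks where the
    stabilization period ends (metrics and severity scores refer to it).
    """
    params = params or PhysiologyParams()
    options = options or SolverOptions()
    dt = options.dt

    times = np.asarray(pattern.times, dtype=float)
    if times.size < 2:
        raise ParameterValidationError("pattern must span at least two samples")
    grid_dt = float(times[1] - times[0])
    if abs(grid_dt - dt) > 1e-12 or np.max(np.abs(np.diff(times) - grid_dt)) > 1e-9:
        # resample the supplied pattern onto the solver grid
        n = int(math.floor((times[-1] - times[0]) / dt)) + 1
        grid = times[0] + np.arange(n) * dt
        V_A = np.interp(grid, times, pattern.V_A)
        dV = np.interp(grid, times, pattern.dV_A_dt)
        times = grid
    else:
        V_A = np.asarray(pattern.V_A, dtype=float)
        dV = np.asarray(pattern.dV_A_dt, dtype=float)
    n = times.size

    Q = _as_q_series(hr, times, params)
    # CFL check up front: no parcel may cross more than one slice per step
    dv_cap = params.V_pc / options.n_slices
    dv_sys = params.V_sys_cap / options.n_systemic_parcels
    q_max = float(np.max(Q))
    if q_max * dt > min(dv_cap, dv_sys):
        raise CFLError(
            f"dt = {dt} s violates the advection constraint; need "
            f"dt <= {min(dv_cap, dv_sys) / q_max:.4g} s at peak cardiac "
            f"output {q_max:.3g} L/s"
        )

    # uniform initial conditions at the resting arterial point
    beta_p = params.beta_p
    C_d0 = beta_p * INITIAL_P_O2
    C_T0 = C_d0 + 4.0 * params.C_Hb * saturation_from_pressure(INITIAL_P_O2)
    profile = CapillaryProfile.uniform(params, C_T0, options.n_slices, C_d0=C_d0)
    systemic = SystemicState.uniform(params, C_T0, options.n_systemic_parcels)

    P_I = inspired_partial_pressure(params)
    k_l, RT, leak = params.k_l, params.RT, params.arteriole_leak_fraction

    P_A = np.empty(n)
    C_pv_T = np.empty(n)
    C_sv_T = np.empty(n)
    uptake = np.zeros(n)
    P_A[0] = INITIAL_P_O2
    C_pv_T[0] = C_T0
    C_sv_T[0] = C_T0

    snapshots: list[CapillarySnapshot] = []
    use_compiled = options.loop == "compiled" or (
        options.loop == "auto" and HAVE_NUMBA and not options.snapshot_times
    )
    if use_compiled and not HAVE_NUMBA:
        raise SimulationError("compiled loop requested but numba is unavailable")
    if use_compiled:
        status, bad_step, clamps, P_A, C_pv_T, C_sv_T, uptake = simulate_loop(
            V_A, dV, Q, dt, P_I, beta_p, params.C_Hb, k_l, RT,
            params.V_pc, params.V_sys_cap, params.MR_O2, leak,
            profile.pos_vol, profile.C_T, profile.C_d,
            systemic.pos_vol, systemic.C_T,
            INITIAL_P_O2, C_T0, C_T0,
        )
        if status != 0:
            raise SimulationError(
                f"alveolar pressure became invalid at step {bad_step} "
                f"(t = {times[bad_step]:.3f} s); reduce dt (currently {dt} s)"
            )
        if clamps:
            logger.warning(
                "systemic O2 consumption clamped %d parcel updates at zero; "
                "parameters are likely unphysiological", clamps,
            )
    else:
        snap_idx = {
            int(round((t - times[0]) / dt)): t for t in options.snapshot_times
        }
        p_a = INITIAL_P_O2
        c_pa_T = C_T0  # systemic outlet feeding the pulmonary arteries
        for k in range(n - 1):
            if k in snap_idx:
                z, P = profile.pressure_profile(params)
                snapshots.append(CapillarySnapshot(times[k], z.copy(), P.copy()))
            c_c_bar = profile.C_c_bar
            c_a = beta_p * p_a
            q = Q[k]
            # alveolar update (inspiration vs expiration regime)
            transfer = k_l * (c_a - c_c_bar) * RT
            dvdt = dV[k]
            if dvdt > 0:
                dp = (dvdt * (P_I - p_a) - transfer) / V_A[k]
            else:
                dp = -transfer / V_A[k]
            p_a += dt * dp
            if not math.isfinite(p_a) or p_a <= 0:
                raise SimulationError(
                    f"alveolar pressure became invalid ({p_a!r}) at step {k} "
                    f"(t = {times[k]:.3f} s); reduce dt (currently {dt} s)"
                )
            # pulmonary capillary uptake + advection
            profile, c_pv_T, upt = advance_capillary(
                profile, c_a, c_pa_T, q, dt, params
            )
            # systemic arterial inlet, with optional arteriolar leak
            c_sa_T = leak * c_pv_T
            systemic, c_pa_T = systemic_transit(systemic, c_sa_T, q, dt, params)
            P_A[k + 1] = p_a
            C_pv_T[k + 1] = c_pv_T
            C_sv_T[k + 1] = c_pa_T
            uptake[k] = upt
        uptake[n - 1] = uptake[n - 2]
        if (n - 1) in snap_idx:
            z, P = profile.pressure_profile(params)
            snapshots.append(CapillarySnapshot(times[n - 1], z.copy(), P.copy()))

    # convert boundary totals to full blood states (vectorized)
    C_sa_T = leak * C_pv_T
    sa_d = dissolved_from_total_array(C_sa_T, params)
    sv_d = dissolved_from_total_array(C_sv_T, params)
    pv_d = dissolved_from_total_array(C_pv_T, params)

    def trace(c_d, c_t):
        P = c_d / beta_p
        return CompartmentTrace(
            C_d=c_d, C_T=c_t, S=saturation_from_pressure(P), P=P
        )

    compartments = {
        "sa": trace(sa_d, C_sa_T),
        "sv": trace(sv_d, C_sv_T),
        "pa": trace(sv_d, C_sv_T),  # large vessels not modeled
        "pv": trace(pv_d, C_pv_T),
    }
    for tag, tr in compartments.items():
        if not np.all(np.isfinite(tr.C_d)):
            raise SimulationError(f"non-finite concentration in {tag} trace")
    return SimulationResult(
        times=times,
        V_A=V_A,
        P_A=P_A,
        compartments=compartments,
        Q=Q,
        uptake_rate=uptake,
        events=tuple(pattern.events),
        scenario_start=scenario_start,
        snapshots=tuple(snapshots),
        params=params,
        options=options,
    )


def run_scenario(
    spec: BreathingSpec,
    params: PhysiologyParams | None = None,
    hr=DEFAULT_HEART_RATE_BPM,
    options: SolverOptions | None = None,
) -> SimulationResult:
    """Stabilize on normal breathing, then run the scenario's events."""
    options = options or SolverOptions()
    pattern = build_pattern(spec, options.dt, include_stabilization=True)
    return run_simulation(
        pattern, params, hr, options, scenario_start=spec.stabilization_time
    )


# ---------------------------------------------------------------------------
# summary metrics


def _window_mask(times: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (times >= lo - 1e-12) & (times <= hi + 1e-12)


def _cycle_smooth(x: np.ndarray, dt: float, window: float) -> np.ndarray:
    """Centered moving average over ~one breath period.

    The compartment traces oscillate within each breath; judging recovery
    against a narrow band only makes sense on the cycle mean, not on the
    raw oscillating signal.
    """
    n = max(1, int(round(window / dt)))
    if n <= 1:
        return x
    kernel = np.ones(n) / n
    pad = n // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad:pad + x.size]


def compute_metrics(
    result: SimulationResult,
    normal_window: tuple[float, float] | None = None,
    *,
    reox_band: float = 0.01,
    analysis_window: tuple[float, float] | None = None,
    smooth_window: float = 5.0,
) -> SummaryMetrics:
    """Severity metrics comparing the scenario to the normal cycle.

    ``normal_window`` delimits the stabilized normal-breathing reference
    (default: the final 60 s of the stabilization period).  Percent
    decreases compare the normal averages to the scenario minima; the
    mass-transfer reduction compares the scenario-averaged systemic
    arteriovenous dissolved-O2 difference to its normal value.  The
    reoxygenation time of an event runs from the post-event minimum until
    both the arterial saturation and dissolved concentration re-enter a
    ``reox_band`` relative band around their normal averages; recovery
    and overshoot are judged on traces smoothed over ``smooth_window``
    seconds (one normal breath period by default) so that the narrow
    band compares cycle means rather than intra-breath oscillation.
    """
    t = result.times
    if normal_window is None:
        hi = result.scenario_start
        normal_window = (max(t[0], hi - 60.0), hi)
    lo, hi = normal_window
    nmask = _window_mask(t, lo, hi)
    if not np.any(nmask):
        raise ParameterValidationError("normal window contains no samples")
    if analysis_window is None:
        analysis_window = (result.scenario_start, float(t[-1]))
    amask = _window_mask(t, *analysis_window)
    if not np.any(amask):
        raise ParameterValidationError("analysis window contains no samples")

    sa, sv = result.compartments["sa"], result.compartments["sv"]
    normal = {
        "S_sa": float(np.mean(sa.S[nmask])),
        "S_sv": float(np.mean(sv.S[nmask])),
        "C_sa_d": float(np.mean(sa.C_d[nmask])),
        "C_sv_d": float(np.mean(sv.C_d[nmask])),
        "P_A": float(np.mean(result.P_A[nmask])),
        "diff_d": float(np.mean(sa.C_d[nmask] - sv.C_d[nmask])),
    }

    def pct_dec(trace_values, key):
        return 100.0 * (normal[key] - float(np.min(trace_values[amask]))) / normal[key]

    pct_sat = {"sa": pct_dec(sa.S, "S_sa"), "sv": pct_dec(sv.S, "S_sv")}
    pct_dis = {"sa": pct_dec(sa.C_d, "C_sa_d"), "sv": pct_dec(sv.C_d, "C_sv_d")}
    mean_diff = float(np.mean(sa.C_d[amask] - sv.C_d[amask]))
    pct_mt = 100.0 * (1.0 - mean_diff / normal["diff_d"])

    s_smooth = _cycle_smooth(sa.S, result.dt, smooth_window)
    cd_smooth = _cycle_smooth(sa.C_d, result.dt, smooth_window)
    respiratory = sorted(
        (e for e in result.events if e.is_respiratory), key=lambda e: e.start
    )
    per_event = []
    for i, ev in enumerate(respiratory):
        w_lo = ev.start
        w_hi = respiratory[i + 1].start if i + 1 < len(respiratory) else analysis_window[1]
        mask = _window_mask(t, w_lo, w_hi)
        if not np.any(mask):
            continue
        idx = np.nonzero(mask)[0]
        j_min = idx[int(np.argmin(sa.C_d[idx]))]
        min_cd = float(sa.C_d[j_min])
        min_s = float(np.min(sa.S[idx]))
        sat_dec = 100.0 * (normal["S_sa"] - min_s) / normal["S_sa"]
        # recovery: both cycle-mean traces back inside the band; the
        # trailing smoothing window is excluded so the next event's onset
        # does not bleed into the judgment
        post = idx[idx >= j_min]
        trim = int(round(smooth_window / result.dt))
        if trim > 0 and post.size > 2 * trim:
            post = post[:-trim]
        in_band = (
            np.abs(s_smooth[post] - normal["S_sa"]) <= reox_band * normal["S_sa"]
        ) & (
            np.abs(cd_smooth[post] - normal["C_sa_d"]) <= reox_band * normal["C_sa_d"]
        )
        hits = np.nonzero(in_band)[0]
        reox = float(t[post[hits[0]]] - t[j_min]) if hits.size else float("nan")
        overshoot = bool(
            np.any(cd_smooth[post] > normal["C_sa_d"] * (1.0 + reox_band))
        )
        per_event.append(
            EventMetrics(
                event=ev,
                t_min_s=float(t[j_min]),
                min_S_sa=min_s,
                min_C_sa_d=min_cd,
                saturation_decrease_pct=sat_dec,
                reoxygenation_time_s=reox,
                overshoot=overshoot,
            )
        )
    return SummaryMetrics(
        normal_avg=normal,
        pct_decrease_saturation=pct_sat,
        pct_decrease_dissolved=pct_dis,
        pct_reduction_mass_transfer=pct_mt,
        per_event=tuple(per_event),
    )


def scored_events(
    metrics: SummaryMetrics,
    *,
    min_duration: float = _breathing.MIN_SCORED_EVENT_DURATION_S,
    hypopnea_desat_pct: float = 4.0,
) -> tuple[EventAnnotation, ...]:
    """Clinically scored subset of the simulated events.

    Apneas must last at least ``min_duration`` s; hypopneas must in
    addition achieve at least ``hypopnea_desat_pct`` percent decrease in
    arterial saturation relative to the normal average.
    """
    out = []
    for m in metrics.per_event:
        ev = m.event
        if ev.duration < min_duration:
            continue
        if ev.kind == "hypopnea" and m.saturation_decrease_pct < hypopnea_desat_pct:
            continue
        out.append(ev)
    return tuple(out)


def ahi_from_result(
    result: SimulationResult, metrics: SummaryMetrics | None = None
) -> float:
    """AHI of the simulated scenario over the post-stabilization period,
    applying the clinical duration and hypopnea-desaturation criteria."""
    metrics = metrics or compute_metrics(result)
    analyzed = float(result.times[-1]) - result.scenario_start
    events = scored_events(metrics)
    return compute_ahi(events, analyzed, apply_duration_filter=False)
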