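"""Systemic capillary transit, oxygen consumption and compartment linkage.

All tissue O2 extraction is lumped into the systemic capillary
compartment: a blood parcel moving with the flow loses total oxygen at
the constant volumetric rate

    dC_cv,T/dt = - MR_O2 / V_sys_cap,

so over a transit (the time for the integrated flow to equal the
compartment volume, \\int Q dt = V_sys_cap) a parcel entering with C_T
exits with C_T - MR_O2 tau / V_sys_cap; at constant flow this is the Fick
principle, delta C_T = MR_O2 / Q.  The large vessels are not modeled:
pulmonary-venous total O2 equals the systemic-arterial value (times an
optional arteriolar leak fraction) and the systemic-venous value equals
the pulmonary-arterial one, so systemic capillary transit is the only
delay between the lungs and the tissues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import CFLError, DataError, ParameterValidationError
from .parameters import PhysiologyParams

logger = logging.getLogger(__name__)

DEFAULT_N_PARCELS = 60


@dataclass
class SystemicState:
    """FIFO of blood parcels in transit through the systemic capillaries."""

    pos_vol: np.ndarray  # cumulative-volume coordinate in [0, V_sys_cap]
    C_T: np.ndarray  # total O2 of each parcel, mol/L
    V_sys_cap: float
    clamp_count: int = 0
    last_outlet_C_T: float = field(default=np.nan)

    @classmethod
    def uniform(
        cls,
        params: PhysiologyParams,
        C_T0: float,
        n_parcels: int = DEFAULT_N_PARCELS,
    ) -> "SystemicState":
        if n_parcels < 1:
            raise ParameterValidationError("need at least one parcel")
        dv = params.V_sys_cap / n_parcels
        pos = (np.arange(n_parcels) + 0.5) * dv
        return cls(
            pos_vol=pos,
            C_T=np.full(n_parcels, float(C_T0)),
            V_sys_cap=params.V_sys_cap,
            last_outlet_C_T=float(C_T0),
        )

    @property
    def dV(self) -> float:
        return self.V_sys_cap / self.pos_vol.size


def systemic_transit(
    state: SystemicState,
    inlet_C_T: float,
    Q: float,
    dt: float,
    params: PhysiologyParams,
):
    """Advance the systemic capillary queue one step (in place).

    ``inlet_C_T`` is the total O2 entering the compartment (the
    arteriole-leak-scaled pulmonary-venous value).  Returns
    ``(state, outlet_C_T)`` where the outlet feeds the pulmonary
    arteries and is held between parcel exits.  Consumption may not
    drive a parcel's total O2 negative; the floor is clamped and
    logged as a sign of unphysiological parameters.
    """
    if dt <= 0 or Q <= 0:
        raise ParameterValidationError("Q and dt must be positive")
    if inlet_C_T < 0:
        raise ParameterValidationError("inlet concentration must be >= 0")
    dv_flow = Q * dt
    if dv_flow > state.dV * (1.0 + 1e-9):
        raise CFLError(
            f"advection Q*dt = {dv_flow:.3e} L exceeds the systemic parcel "
            f"volume {state.dV:.3e} L; reduce dt"
        )
    state.C_T -= params.MR_O2 / params.V_sys_cap * dt
    negative = state.C_T < 0
    if np.any(negative):
        state.C_T[negative] = 0.0
        if state.clamp_count == 0:
            logger.warning(
                "systemic O2 consumption drove a parcel to zero total "
                "oxygen; parameters are likely unphysiological"
            )
        state.clamp_count += int(np.count_nonzero(negative))
    state.pos_vol += dv_flow
    exiting = np.nonzero(state.pos_vol >= state.V_sys_cap)[0]
    for i in exiting:
        state.last_outlet_C_T = float(state.C_T[i])
        state.pos_vol[i] -= state.V_sys_cap
        state.C_T[i] = inlet_C_T
    return state, state.last_outlet_C_T


def cardiac_output_from_heart_rate(
    hr,
    params: PhysiologyParams,
    *,
    smooth_window: int | None = None,
):
    """Convert a heart-rate series (beats/min) to cardiac output (L/s).

    Q(t) = hr(t) * stroke_volume / 60.  ``smooth_window`` applies an
    optional centered moving average (in samples) to suppress beat-to-beat
    jitter before conversion.
    """
    scalar_input = np.ndim(hr) == 0
    hr = np.atleast_1d(np.asarray(hr, dtype=float))
    bad = np.nonzero(~(hr > 0))[0]
    if bad.size:
        raise DataError(
            f"non-positive heart rate at sample index {int(bad[0])}: "
            f"{hr.flat[bad[0]]!r}"
        )
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(hr, pad, mode="edge")
        hr = np.convolve(padded, kernel, mode="same")[pad:pad + hr.size]
    q = hr * params.stroke_volume / 60.0
    return float(q[0]) if scalar_input else q
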