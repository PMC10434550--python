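"""Alveolar compartment oxygen mass balance.

The alveoli are a single well-mixed gas compartment whose volume V_A(t) is
prescribed by the breathing pattern.  Inspired air is ideal, water-vapor
saturated at body temperature, so the inspired O2 partial pressure is
P_I = y_O2 (P_B - P_H2O).  During inspiration (dV_A/dt > 0) fresh gas at
P_I mixes in while dissolved O2 crosses the alveolar-capillary membrane:

    V_A dP_A/dt = dV_A/dt (P_I - P_A) - k_l (C_A - C_c) R T,

and during expiration (dV_A/dt <= 0) gas leaves at alveolar composition
so only membrane transfer changes the partial pressure:

    V_A dP_A/dt = - k_l (C_A - C_c) R T,

with C_A = beta_p P_A the dissolved O2 at the membrane, C_c the spatial
average over the pulmonary capillary compartment and k_l = D_L_O2/beta_p.
The two regimes coincide at dV_A/dt = 0; the expiration form is used at
exactly zero flow.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterValidationError, SimulationError
from .parameters import PhysiologyParams


@dataclass(frozen=True)
class AlveolarState:
    """Alveolar O2 partial pressure (mmHg) and current volume (L)."""

    P_A: float
    V_A: float

    def C_A(self, params: PhysiologyParams) -> float:
        """Dissolved O2 concentration in the alveolar membrane, mol/L."""
        return params.beta_p * self.P_A


def inspired_partial_pressure(params: PhysiologyParams) -> float:
    """Inspired (tracheal) O2 partial pressure y_O2 (P_B - P_H2O), mmHg."""
    if params.P_H2O >= params.P_B:
        raise ParameterValidationError(
            "water vapor pressure must be below barometric pressure"
        )
    return params.y_O2 * (params.P_B - params.P_H2O)


def alveolar_rhs(
    state: AlveolarState,
    dV_A_dt: float,
    C_c_bar: float,
    params: PhysiologyParams,
    P_I: float | None = None,
) -> float:
    """Rate of change of alveolar O2 partial pressure, mmHg/s.

    ``C_c_bar`` is the spatially averaged dissolved O2 in the pulmonary
    capillary compartment (mol/L), supplied by the capillary model at the
    previous time level (explicit coupling).
    """
    if state.V_A <= 0:
        raise SimulationError(f"non-physical alveolar volume {state.V_A!r} L")
    if P_I is None:
        P_I = inspired_partial_pressure(params)
    transfer = params.k_l * (params.beta_p * state.P_A - C_c_bar) * params.RT
    if dV_A_dt > 0:
        return (dV_A_dt * (P_I - state.P_A) - transfer) / state.V_A
    return -transfer / state.V_A
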