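"""Spatial oxygen uptake along the pulmonary capillary compartment.

Blood is tracked as a FIFO queue of Lagrangian control volumes (parcels)
of equal blood volume dV = V_pc / N_slices that advect through the
compartment with the pulmonary blood flow and exchange oxygen with the
(spatially uniform) alveolar membrane:

    dV dC_cv,T/dt = k_pc (C_A - C_cv,d),      k_pc = (D_L_O2/beta_p) dz/L_c,

where dz = L_c / N_slices is the parcel length, so the per-parcel
relaxation constant k_pc/dV = k_l / V_pc is uniform along the compartment.
Each parcel's total O2 concentration is spatially uniform; its dissolved
concentration follows from the hemoglobin equilibrium.  The Lagrangian
queue eliminates numerical diffusion: a parcel entering at z = 0 with the
pulmonary-arterial concentration exits at z = L_c exactly one blood
transit time V_pc/Q later, defining the pulmonary-venous concentration.

Positions are carried in a cumulative-blood-volume coordinate in
[0, V_pc]; the geometric coordinate is z = (position/V_pc) L_c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CFLError, NumericalError, ParameterValidationError
from .hemoglobin import dissolved_from_total_array, saturation_from_pressure
from .parameters import PhysiologyParams

DEFAULT_N_SLICES = 40


@dataclass(frozen=True)
class ControlVolume:
    """One blood parcel: position along the compartment and its O2 state."""

    position: float  # m along [0, L_c]
    C_T: float  # total O2, mol/L
    C_d: float  # dissolved O2, mol/L
    volume: float  # blood volume dV, L


@dataclass
class CapillaryProfile:
    """Ordered parcel queue filling the pulmonary capillary compartment.

    ``pos_vol`` holds each parcel's cumulative-volume coordinate in
    [0, V_pc]; arrays are ordered entrance -> exit is *not* guaranteed by
    index (the queue is circular), use :meth:`parcels` for an ordered view.
    """

    pos_vol: np.ndarray
    C_T: np.ndarray
    C_d: np.ndarray
    V_pc: float
    L_c: float
    exit_count: int = 0
    last_outlet_C_T: float = field(default=np.nan)

    @classmethod
    def uniform(
        cls,
        params: PhysiologyParams,
        C_T0: float,
        n_slices: int = DEFAULT_N_SLICES,
        C_d0: float | None = None,
    ) -> "CapillaryProfile":
        """Compartment filled with parcels at a single total concentration."""
        if n_slices < 1:
            raise ParameterValidationError("need at least one slice")
        dv = params.V_pc / n_slices
        pos = (np.arange(n_slices) + 0.5) * dv
        C_T = np.full(n_slices, float(C_T0))
        if C_d0 is None:
            C_d = dissolved_from_total_array(C_T, params)
        else:
            C_d = np.full(n_slices, float(C_d0))
        return cls(
            pos_vol=pos, C_T=C_T, C_d=C_d, V_pc=params.V_pc, L_c=params.L_c,
            last_outlet_C_T=float(C_T0),
        )

    @property
    def n_slices(self) -> int:
        return self.pos_vol.size

    @property
    def dV(self) -> float:
        """Blood volume per parcel, L."""
        return self.V_pc / self.n_slices

    @property
    def C_c_bar(self) -> float:
        """Spatially averaged dissolved O2 (equal parcel volumes), mol/L."""
        return float(np.mean(self.C_d))

    def parcels(self) -> list[ControlVolume]:
        """Parcels ordered by position (entrance to exit)."""
        order = np.argsort(self.pos_vol)
        scale = self.L_c / self.V_pc
        return [
            ControlVolume(
                position=float(self.pos_vol[i]) * scale,
                C_T=float(self.C_T[i]),
                C_d=float(self.C_d[i]),
                volume=self.dV,
            )
            for i in order
        ]

    def pressure_profile(self, params: PhysiologyParams):
        """(z_m, P_mmHg) arrays ordered along the compartment."""
        order = np.argsort(self.pos_vol)
        z = self.pos_vol[order] * (self.L_c / self.V_pc)
        P = self.C_d[order] / params.beta_p
        return z, P


def spatial_average(profile: CapillaryProfile) -> float:
    """Volume-weighted mean dissolved O2 over the compartment, mol/L.

    Approximates (1/L_c) \\int_0^{L_c} C_pc,d(z) dz; parcels have equal
    volume so this is a plain mean.
    """
    if profile.n_slices == 0:
        raise ParameterValidationError("empty capillary compartment")
    return profile.C_c_bar


def advance_capillary(
    profile: CapillaryProfile,
    C_A: float,
    inlet_C_T: float,
    Q: float,
    dt: float,
    params: PhysiologyParams,
):
    """Advance the parcel queue by one explicit time step (in place).

    Returns ``(profile, outlet_C_T, uptake_rate)`` where ``outlet_C_T``
    is the total concentration of the most recently exited parcel (the
    pulmonary-venous boundary value, held between exits) and
    ``uptake_rate`` the molar O2 flux across the membrane (mol/s),
    evaluated at the pre-update state so that it matches the alveolar
    side of the explicit coupling exactly.
    """
    if dt <= 0 or Q <= 0:
        raise ParameterValidationError("Q and dt must be positive")
    dv_flow = Q * dt
    if dv_flow > profile.dV * (1.0 + 1e-9):
        raise CFLError(
            f"advection Q*dt = {dv_flow:.3e} L exceeds the slice volume "
            f"{profile.dV:.3e} L; reduce dt below "
            f"{profile.dV / Q:.3e} s or coarsen the grid"
        )
    # membrane uptake at the current state (explicit, mass-matched with Eq 5)
    uptake_rate = params.k_l * (C_A - profile.C_c_bar)
    profile.C_T += (params.k_l / params.V_pc) * dt * (C_A - profile.C_d)
    if np.any(profile.C_T < 0):
        raise NumericalError("negative total O2 concentration in capillary")
    profile.C_d = dissolved_from_total_array(
        profile.C_T, params, C_d_guess=profile.C_d, iterations=40
    )
    # advect; parcels past V_pc exit and are reborn at the entrance
    profile.pos_vol += dv_flow
    exiting = np.nonzero(profile.pos_vol >= profile.V_pc)[0]
    for i in exiting:  # CFL guarantees at most one per step
        profile.last_outlet_C_T = float(profile.C_T[i])
        profile.pos_vol[i] -= profile.V_pc
        profile.C_T[i] = inlet_C_T
        profile.C_d[i] = dissolved_from_total_array(
            np.array([inlet_C_T]), params,
            C_d_guess=np.array([profile.C_d[i]]),
        )[0]
        profile.exit_count += 1
    return profile, profile.last_outlet_C_T, float(uptake_rate)


def end_capillary_pressure(profile: CapillaryProfile, params: PhysiologyParams) -> float:
    """O2 partial pressure of the parcel nearest the exit, mmHg."""
    i = int(np.argmax(profile.pos_vol))
    return float(profile.C_d[i] / params.beta_p)


def saturation_profile(profile: CapillaryProfile, params: PhysiologyParams):
    """(z_m, S) arrays along the compartment (convenience for figures)."""
    z, P = profile.pressure_profile(params)
    return z, saturation_from_pressure(P)
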