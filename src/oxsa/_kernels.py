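"""Compiled fast path for the coupled time-stepping loop.

The physics here mirrors, operation for operation, the reference
implementations in :mod:`oxsa.alveolar`, :mod:`oxsa.capillary` and
:mod:`oxsa.circulation`; a dedicated test asserts step-level agreement
between the two paths.  If numba is unavailable the simulator falls back
to the (much slower) pure-Python path transparently.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]

# Dissociation-curve fit constants (duplicated from oxsa.hemoglobin so the
# kernel has no Python-object dependencies; a test pins them equal).
_ODC_A = 23_400.0
_ODC_B = 150.0


@njit(cache=True)
def _invert_total(ct, guess, beta_p, four_chb):
    """Scalar safeguarded-Newton inversion of C_T = C_d + 4 C_Hb S."""
    if ct <= 0.0:
        return 0.0
    lo = 0.0
    hi = ct
    x = guess
    if x <= lo or x >= hi:
        x = 0.5 * ct
    for _ in range(100):
        P = x / beta_p
        g = P * (P * P + _ODC_B)
        S = g / (g + _ODC_A)
        f = x + four_chb * S - ct
        if abs(f) < 1e-12:
            return x
        if f > 0.0:
            hi = x
        else:
            lo = x
        dS = _ODC_A * (3.0 * P * P + _ODC_B) / ((g + _ODC_A) * (g + _ODC_A))
        xn = x - f / (1.0 + four_chb * dS / beta_p)
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        x = xn
    return x


@njit(cache=True)
def simulate_loop(
    V_A,
    dV,
    Q,
    dt,
    P_I,
    beta_p,
    C_Hb,
    k_l,
    RT,
    V_pc,
    V_sys,
    MR_O2,
    leak,
    cap_pos,
    cap_ct,
    cap_cd,
    sys_pos,
    sys_ct,
    P_A0,
    C_pv0,
    C_sv0,
):
    """Advance the coupled model over the whole grid.

    Mutates the parcel arrays in place and returns
    (status, bad_step, clamp_count, P_A, C_pv_T, C_sv_T, uptake);
    status 1 flags a non-finite/non-positive alveolar pressure.
    """
    n = V_A.size
    n_cap = cap_pos.size
    n_sys = sys_pos.size
    four_chb = 4.0 * C_Hb
    P_A = np.empty(n)
    C_pv_T = np.empty(n)
    C_sv_T = np.empty(n)
    uptake = np.zeros(n)
    P_A[0] = P_A0
    C_pv_T[0] = C_pv0
    C_sv_T[0] = C_sv0
    p_a = P_A0
    c_pv_T = C_pv0
    c_pa_T = C_sv0
    clamp_count = 0
    status = 0
    bad_step = -1
    cons = MR_O2 / V_sys * dt
    rate = k_l / V_pc * dt
    for k in range(n - 1):
        q = Q[k]
        dvf = q * dt
        # alveolar regime split, using the previous-level capillary average
        s = 0.0
        for i in range(n_cap):
            s += cap_cd[i]
        c_c_bar = s / n_cap
        c_a = beta_p * p_a
        transfer = k_l * (c_a - c_c_bar) * RT
        if dV[k] > 0.0:
            dp = (dV[k] * (P_I - p_a) - transfer) / V_A[k]
        else:
            dp = -transfer / V_A[k]
        uptake[k] = k_l * (c_a - c_c_bar)
        p_a = p_a + dt * dp
        if not np.isfinite(p_a) or p_a <= 0.0:
            status = 1
            bad_step = k
            break
        # pulmonary capillary parcels: uptake, equilibrium, advection
        for i in range(n_cap):
            ct = cap_ct[i] + rate * (c_a - cap_cd[i])
            cap_ct[i] = ct
            cap_cd[i] = _invert_total(ct, cap_cd[i], beta_p, four_chb)
            cap_pos[i] += dvf
            if cap_pos[i] >= V_pc:
                c_pv_T = cap_ct[i]
                cap_pos[i] -= V_pc
                cap_ct[i] = c_pa_T
                cap_cd[i] = _invert_total(c_pa_T, cap_cd[i], beta_p, four_chb)
        c_sa_T = leak * c_pv_T
        # systemic capillary parcels: consumption + advection
        for i in range(n_sys):
            v = sys_ct[i] - cons
            if v < 0.0:
                v = 0.0
                clamp_count += 1
            sys_ct[i] = v
            sys_pos[i] += dvf
            if sys_pos[i] >= V_sys:
                out = sys_ct[i]
                sys_pos[i] -= V_sys
                sys_ct[i] = c_sa_T
                c_pa_T = out
        P_A[k + 1] = p_a
        C_pv_T[k + 1] = c_pv_T
        C_sv_T[k + 1] = c_pa_T
    if n >= 2:
        uptake[n - 1] = uptake[n - 2]
    return status, bad_step, clamp_count, P_A, C_pv_T, C_sv_T, uptake
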