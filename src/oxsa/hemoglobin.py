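"""Oxygen-hemoglobin chemistry.

The saturation curve is the classic one-term rational fit to the standard
oxygen-hemoglobin dissociation curve,

    S(P) = [1 + 23400 / (P^3 + 150 P)]^(-1),

with P in mmHg.  Total blood O2 content is the dissolved fraction plus the
hemoglobin-bound fraction (four binding sites per hemoglobin):

    C_T = C_d + 4 C_Hb S(C_d / beta_p).

Because C_T is strictly increasing in C_d, the inverse map (total ->
dissolved) is unique; it is computed with a safeguarded Newton iteration
that falls back to bisection on the bracket [0, C_T].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError, ParameterValidationError
from .parameters import PhysiologyParams

#: Constants of the published dissociation-curve fit (mmHg^3, mmHg^2).
#: They define the curve and are deliberately not configurable.
ODC_A = 23_400.0
ODC_B = 150.0

#: Compartment tags: pulmonary arteries / capillaries / veins,
#: systemic arteries / veins.
COMPARTMENT_TAGS = ("pa", "pc", "pv", "sa", "sv")


@dataclass(frozen=True)
class BloodState:
    """Consistent O2 state of blood in one compartment at one instant.

    ``C_d`` dissolved and ``C_T`` total concentration (mol/L of blood),
    ``S`` hemoglobin saturation fraction, ``P`` partial pressure (mmHg).
    """

    C_d: float
    C_T: float
    S: float
    P: float
    compartment_tag: str | None = None

    def __post_init__(self) -> None:
        if self.compartment_tag is not None and self.compartment_tag not in COMPARTMENT_TAGS:
            raise ParameterValidationError(
                f"unknown compartment tag {self.compartment_tag!r}; "
                f"expected one of {COMPARTMENT_TAGS}"
            )


def saturation_from_pressure(P):
    """Hemoglobin saturation fraction at O2 partial pressure ``P`` (mmHg).

    Accepts scalars or arrays.  S(0) = 0; S increases monotonically and
    approaches 1 as P grows.  Negative pressures are a domain error.
    """
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ParameterValidationError("partial pressure must be non-negative")
    g = P * (P * P + ODC_B)  # P^3 + 150 P, algebraically safe at P = 0
    S = g / (g + ODC_A)
    return float(S) if S.ndim == 0 else S


def saturation_slope(P):
    """dS/dP of the dissociation curve at ``P`` (mmHg⁻¹)."""
    P = np.asarray(P, dtype=float)
    g = P * (P * P + ODC_B)
    dg = 3.0 * P * P + ODC_B
    out = ODC_A * dg / (g + ODC_A) ** 2
    return float(out) if out.ndim == 0 else out


def total_from_dissolved(
    C_d: float, params: PhysiologyParams, compartment_tag: str | None = None
) -> BloodState:
    """Full blood state from the dissolved concentration (mol/L)."""
    if C_d < 0:
        raise ParameterValidationError("dissolved concentration must be >= 0")
    P = C_d / params.beta_p
    S = saturation_from_pressure(P)
    C_T = C_d + 4.0 * params.C_Hb * S
    return BloodState(C_d=C_d, C_T=C_T, S=S, P=P, compartment_tag=compartment_tag)


def dissolved_from_total(
    C_T: float,
    params: PhysiologyParams,
    compartment_tag: str | None = None,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> BloodState:
    """Invert C_T = C_d + 4 C_Hb S(C_d/beta_p) for the unique C_d >= 0.

    Safeguarded Newton iteration on the bracket [0, C_T] with bisection
    fallback; ``tol`` is an absolute tolerance on the residual in mol/L.
    """
    if C_T < 0:
        raise ParameterValidationError("total concentration must be >= 0")
    if C_T == 0.0:
        return BloodState(0.0, 0.0, 0.0, 0.0, compartment_tag)

    lo, hi = 0.0, C_T  # f(lo) <= 0, f(hi) >= 0 since the bound term is >= 0
    x = 0.5 * C_T
    for _ in range(max_iter):
        P = x / params.beta_p
        f = x + 4.0 * params.C_Hb * saturation_from_pressure(P) - C_T
        if abs(f) < tol:
            break
        if f > 0:
            hi = x
        else:
            lo = x
        df = 1.0 + 4.0 * params.C_Hb * saturation_slope(P) / params.beta_p
        step = x - f / df
        # keep the iterate inside the shrinking bracket, else bisect
        x = step if lo < step < hi else 0.5 * (lo + hi)
    else:
        raise NumericalError(
            "dissolved_from_total did not converge: "
            f"bracket [{lo:.3e}, {hi:.3e}], residual {f:.3e} mol/L"
        )
    return total_from_dissolved(x, params, compartment_tag)


def dissolved_from_total_array(
    C_T: np.ndarray,
    params: PhysiologyParams,
    *,
    C_d_guess: np.ndarray | None = None,
    iterations: int = 60,
    tol: float = 1e-12,
) -> np.ndarray:
    """Vectorized inversion of the total->dissolved map.

    Damped Newton iteration clipped to the bracket [0, C_T]; Newton is
    globally convergent here because C_T(C_d) is increasing and concave
    changes sign only once.  A warm start ``C_d_guess`` (e.g. the value
    from the previous time step) makes per-step convergence essentially
    immediate; the iteration exits early once the worst residual is
    below ``tol``.
    """
    C_T = np.asarray(C_T, dtype=float)
    lo = np.zeros_like(C_T)
    hi = C_T.copy()
    if C_d_guess is not None:
        x = np.clip(np.asarray(C_d_guess, dtype=float), 0.0, C_T)
    else:
        x = 0.5 * C_T
    four_chb = 4.0 * params.C_Hb
    inv_bp = 1.0 / params.beta_p
    for _ in range(iterations):
        P = x * inv_bp
        g = P * (P * P + ODC_B)
        S = g / (g + ODC_A)
        f = x + four_chb * S - C_T
        active = np.abs(f) >= tol  # converged elements must not move again
        if not np.any(active):
            break
        hi = np.where(active & (f > 0), x, hi)
        lo = np.where(active & (f <= 0), x, lo)
        dS = ODC_A * (3.0 * P * P + ODC_B) / (g + ODC_A) ** 2
        newton = x - f / (1.0 + four_chb * dS * inv_bp)
        inside = (newton > lo) & (newton < hi)
        x = np.where(active, np.where(inside, newton, 0.5 * (lo + hi)), x)
    return x
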