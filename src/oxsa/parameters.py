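"""Registry of physiological constants with unit discipline and validation.

All values are stored internally in a single consistent unit system:
moles, litres, seconds, mmHg and kelvin.  Configuration files may declare
each field either as a bare number (interpreted in the internal units) or
as a ``{value: x, units: "..."}`` mapping using one of the recognized
clinical unit strings (e.g. the lung diffusing capacity is conventionally
reported in mL O2·min⁻¹·mmHg⁻¹ at STPD and is converted on load).

Defaults describe a healthy adult at rest and are calibrated so that the
closed circulatory loop settles at textbook resting oxygenation
(arterial P_O2 ≈ 99 mmHg, venous ≈ 41 mmHg, cardiac output ≈ 5.3 L/min,
O2 consumption ≈ 250 mL/min).  Every default is overridable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError, ParameterValidationError, UnitError

#: mL of gas per mole at standard temperature and pressure, dry (STPD).
#: Used once, for the conventional gas-volume reporting of diffusing
#: capacity and metabolic rate.
ML_GAS_PER_MOL = 22_400.0

#: Ideal gas constant in L·mmHg·mol⁻¹·K⁻¹.
R_L_MMHG = 62.36367


def _ml_min_mmhg_to_mol_s_mmhg(x: float) -> float:
    return x / ML_GAS_PER_MOL / 60.0


# Per-field unit tables: unit string -> multiplicative factor to internal units.
_UNIT_TABLES: dict[str, dict[str, float]] = {
    "D_L_O2": {
        "mol/(s*mmHg)": 1.0,
        "mL/(min*mmHg)": 1.0 / ML_GAS_PER_MOL / 60.0,
    },
    "beta_p": {"mol/(L*mmHg)": 1.0, "uM/mmHg": 1e-6},
    "C_Hb": {"mol/L": 1.0, "mM": 1e-3, "uM": 1e-6},
    "MR_O2": {"mol/s": 1.0, "mL/min": 1.0 / ML_GAS_PER_MOL / 60.0},
    "V_sys_cap": {"L": 1.0, "mL": 1e-3},
    "V_pc": {"L": 1.0, "mL": 1e-3},
    "A_eff": {"m^2": 1.0, "cm^2": 1e-4},
    "P_B": {"mmHg": 1.0},
    "P_H2O": {"mmHg": 1.0},
    "y_O2": {"fraction": 1.0},
    "R": {"L*mmHg/(mol*K)": 1.0},
    "T": {"K": 1.0},
    "stroke_volume": {"L": 1.0, "mL": 1e-3},
    "arteriole_leak_fraction": {"fraction": 1.0},
}


@dataclass(frozen=True)
class PhysiologyParams:
    """Validated physiological parameter set (internal units).

    Attributes
    ----------
    D_L_O2 : float
        Lung O2 diffusing capacity, mol·s⁻¹·mmHg⁻¹ (default corresponds to
        21 mL O2·min⁻¹·mmHg⁻¹, the resting value for a normal subject).
    beta_p : float
        O2 solubility in the alveolar-capillary membrane and blood plasma,
        mol·L⁻¹·mmHg⁻¹ (assumed identical in membrane and plasma).
    C_Hb : float
        Blood hemoglobin concentration, mol·L⁻¹ (4 O2 binding sites each).
    MR_O2 : float
        Total basal metabolic O2 consumption rate, mol·s⁻¹.
    V_sys_cap : float
        Volume of the lumped systemic capillary compartment, L.  Because
        the model equates pulmonary-venous with systemic-arterial and
        systemic-venous with pulmonary-arterial oxygen, this single
        compartment stands in for the *entire* systemic circulation; its
        default is therefore an effective circulating reservoir volume
        (blood pool plus perfused tissue stores), calibrated to resting
        recirculation dynamics, not the anatomic capillary volume.
    V_pc : float
        Total pulmonary capillary blood volume, L.
    A_eff : float
        Effective combined pulmonary capillary cross-section, m²; enters
        only through the compartment length ``L_c = V_pc / A_eff``.
    P_B, P_H2O : float
        Barometric pressure and water vapor pressure at body
        temperature, mmHg.
    y_O2 : float
        Inspired O2 mole fraction (dry gas), in (0, 1).
    R, T : float
        Ideal gas constant (L·mmHg·mol⁻¹·K⁻¹) and body temperature (K).
    stroke_volume : float
        Volume ejected per heart beat, L (converts heart rate to
        cardiac output).
    arteriole_leak_fraction : float
        Fraction of pulmonary-venous total O2 reaching the systemic
        capillaries, in (0, 1]; 1 means no arteriolar leak.
    """

    D_L_O2: float = _ml_min_mmhg_to_mol_s_mmhg(21.0)
    beta_p: float = 1.4e-6
    C_Hb: float = 2.3e-3
    MR_O2: float = 1.83e-4
    V_sys_cap: float = 8.0
    V_pc: float = 0.07
    A_eff: float = 0.07
    P_B: float = 760.0
    P_H2O: float = 47.0
    y_O2: float = 0.21
    R: float = R_L_MMHG
    T: float = 310.0
    stroke_volume: float = 0.07
    arteriole_leak_fraction: float = 1.0
    #: per-field provenance, "default" or "user" (not compared or hashed)
    provenance: Mapping[str, str] = field(
        default_factory=dict, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        positive = (
            "D_L_O2", "beta_p", "C_Hb", "MR_O2", "V_sys_cap", "V_pc",
            "A_eff", "P_B", "P_H2O", "R", "T", "stroke_volume",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterValidationError(
                    f"parameter {name!r} must be strictly positive, "
                    f"got {getattr(self, name)!r}"
                )
        if not 0.0 < self.y_O2 < 1.0:
            raise ParameterValidationError(
                f"y_O2 must be a mole fraction in (0, 1), got {self.y_O2!r}"
            )
        if not 0.0 < self.arteriole_leak_fraction <= 1.0:
            raise ParameterValidationError(
                "arteriole_leak_fraction must lie in (0, 1], got "
                f"{self.arteriole_leak_fraction!r}"
            )
        if self.P_H2O >= self.P_B:
            raise ParameterValidationError(
                "water vapor pressure must be below barometric pressure"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def k_l(self) -> float:
        """Lung mass-transfer coefficient D_L_O2 / beta_p, L·s⁻¹."""
        return self.D_L_O2 / self.beta_p

    @property
    def L_c(self) -> float:
        """Pulmonary capillary compartment length V_pc / A_eff, m."""
        return self.V_pc * 1e-3 / self.A_eff  # L -> m^3

    @property
    def RT(self) -> float:
        """R·T, L·mmHg·mol⁻¹."""
        return self.R * self.T

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict[str, float]:
        d = dataclasses.asdict(self)
        d.pop("provenance")
        return d

    def save(self, path: str | Path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=True))
        else:
            path.write_text(json.dumps(doc, sort_keys=True, indent=1))


def load_params(
    config: Mapping[str, Any] | None = None,
    *,
    strict: bool = True,
) -> PhysiologyParams:
    """Build a validated :class:`PhysiologyParams` from a key-value document.

    Each value may be a number (internal units assumed) or a mapping
    ``{"value": x, "units": "<unit string>"}``.  Unknown keys raise a
    :class:`~oxsa.errors.ConfigurationError` in strict mode and are
    logged as warnings otherwise.  Provenance (default vs user) is
    recorded per field.
    """
    config = dict(config or {})
    fields = {f.name for f in dataclasses.fields(PhysiologyParams)} - {"provenance"}
    unknown = set(config) - fields
    if unknown:
        if strict:
            raise ConfigurationError(
                f"unknown parameter keys: {sorted(unknown)}; "
                f"known keys are {sorted(fields)}"
            )
        import logging

        logging.getLogger(__name__).warning(
            "ignoring unknown parameter keys: %s", sorted(unknown)
        )
        for key in unknown:
            config.pop(key)

    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for name in fields:
        if name not in config:
            provenance[name] = "default"
            continue
        raw = config[name]
        if isinstance(raw, Mapping):
            try:
                value = float(raw["value"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigurationError(
                    f"field {name!r}: expected a 'value' entry, got {raw!r}"
                ) from exc
            units = raw.get("units")
            if units is not None:
                table = _UNIT_TABLES[name]
                if units not in table:
                    raise UnitError(
                        f"field {name!r}: unit {units!r} not recognized; "
                        f"accepted units: {sorted(table)}"
                    )
                value *= table[units]
        else:
            try:
                value = float(raw)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(
                    f"field {name!r}: expected a number, got {raw!r}"
                ) from exc
        values[name] = value
        provenance[name] = "user"
    return PhysiologyParams(provenance=provenance, **values)


def load_params_file(path: str | Path, *, strict: bool = True) -> PhysiologyParams:
    """Load parameters from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return load_params(doc, strict=strict)
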