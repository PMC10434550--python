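"""Bundled breathing scenarios: the normal-subject and severe-OSA
validation patterns plus nine simulated OSA variants used for severity
analysis.  Scenario files are plain YAML and can serve as templates for
user-defined patterns."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .breathing import BreathingSpec, EventAnnotation
from .errors import ConfigurationError

_PACKAGE_DIR = "scenarios"


def _scenario_dir():
    return resources.files(__package__) / _PACKAGE_DIR


def list_scenarios() -> list[str]:
    """Names of the bundled scenarios."""
    return sorted(
        p.name.removesuffix(".yaml")
        for p in _scenario_dir().iterdir()
        if p.name.endswith(".yaml")
    )


def spec_from_dict(doc: dict) -> BreathingSpec:
    """Build a :class:`BreathingSpec` from a scenario document."""
    try:
        events = tuple(
            EventAnnotation(
                kind=e["kind"],
                start=float(e["start_s"]),
                duration=float(e["duration_s"]),
                airflow_fraction=float(e.get("airflow_fraction", 0.0)),
                override_V_T=e.get("override_V_T"),
                override_b_r=e.get("override_b_r"),
            )
            for e in doc.get("events", [])
        )
        return BreathingSpec(
            V_T=float(doc["V_T"]),
            V_D=float(doc["V_D"]),
            V_End=float(doc["V_End"]),
            b_r=float(doc["b_r"]),
            total_duration=float(doc["duration_s"]),
            stabilization_time=float(doc.get("stabilization_s", 360.0)),
            events=events,
        )
    except KeyError as exc:
        raise ConfigurationError(f"scenario document missing field {exc}") from exc


def load_scenario(name_or_path: str | Path) -> BreathingSpec:
    """Load a bundled scenario by name or any scenario YAML by path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        doc = yaml.safe_load(path.read_text())
    else:
        name = str(name_or_path).removesuffix(".yaml")
        res = _scenario_dir() / f"{name}.yaml"
        try:
            doc = yaml.safe_load(res.read_text())
        except FileNotFoundError:
            raise ConfigurationError(
                f"no bundled scenario {name!r}; available: {list_scenarios()}"
            ) from None
    return spec_from_dict(doc)


def scenario_description(name: str) -> str:
    res = _scenario_dir() / f"{name}.yaml"
    return yaml.safe_load(res.read_text()).get("description", "").strip()
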