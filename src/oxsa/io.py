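"""File input/output: time-series CSV, annotation CSV, EDF channels,
configuration documents and run manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breathing import EventAnnotation
from .errors import ConfigurationError, FormatError
from .patient import NasalPressureRecord

logger = logging.getLogger(__name__)


def read_timeseries_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column numeric CSV (time, value) with a header row.

    Times must be strictly increasing; sampling gaps larger than twice
    the median spacing are reported in the log.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected at least two columns")
    for col in df.columns[:2]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(f"{path}: non-numeric cell in column {col!r} at line {line}")
        df[col] = coerced
    times = df.iloc[:, 0].to_numpy(float)
    values = df.iloc[:, 1].to_numpy(float)
    dts = np.diff(times)
    if np.any(dts <= 0):
        line = int(np.nonzero(dts <= 0)[0][0]) + 3
        raise FormatError(f"{path}: time is not strictly increasing at line {line}")
    if dts.size:
        med = float(np.median(dts))
        gaps = np.nonzero(dts > 2.0 * med)[0]
        for g in gaps:
            logger.warning(
                "%s: sampling gap of %.3f s (median %.3f s) at t = %.3f s",
                path, dts[g], med, times[g],
            )
    return times, values


def write_timeseries_csv(path: str | Path, times, values, names=("time_s", "value")):
    # %.17g preserves float64 exactly, so files round-trip bit-identically
    pd.DataFrame({names[0]: times, names[1]: values}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_annotations_csv(path: str | Path) -> tuple[EventAnnotation, ...]:
    """Annotation CSV with columns start_s, duration_s, kind and optional
    airflow_fraction / override_V_T / override_b_r."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"start_s", "duration_s", "kind"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(required)}")
    events = []
    for _, row in df.iterrows():
        kwargs = {}
        if "airflow_fraction" in df.columns and not pd.isna(row["airflow_fraction"]):
            kwargs["airflow_fraction"] = float(row["airflow_fraction"])
        for opt in ("override_V_T", "override_b_r"):
            if opt in df.columns and not pd.isna(row[opt]):
                kwargs[opt] = float(row[opt])
        events.append(
            EventAnnotation(
                kind=str(row["kind"]),
                start=float(row["start_s"]),
                duration=float(row["duration_s"]),
                **kwargs,
            )
        )
    return tuple(events)


def write_annotations_csv(path: str | Path, events) -> None:
    pd.DataFrame(
        [
            {
                "start_s": e.start,
                "duration_s": e.duration,
                "kind": e.kind,
                "airflow_fraction": e.airflow_fraction,
                "override_V_T": e.override_V_T,
                "override_b_r": e.override_b_r,
            }
            for e in events
        ]
    ).to_csv(path, index=False)


_EDF_EVENT_KINDS = {"apnea", "hypopnea", "hyperventilation", "rera", "wake"}


def read_edf_channel(path: str | Path, channel_label: str) -> NasalPressureRecord:
    """Read one signal channel (and any annotations) from an EDF/EDF+ file.

    Annotation descriptions matching known event kinds (case-insensitive)
    are mapped to :class:`~oxsa.breathing.EventAnnotation`; others are
    kept verbatim as sleep-stage style labels.
    """
    import mne  # deferred: EDF support is optional at runtime

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=False, verbose="error")
    if channel_label not in raw.ch_names:
        raise FormatError(
            f"{path}: channel {channel_label!r} not present; "
            f"available channels: {raw.ch_names}"
        )
    raw = raw.copy().pick([channel_label]).load_data(verbose="error")
    data = raw.get_data()[0]
    fs = float(raw.info["sfreq"])
    times = np.arange(data.size) / fs
    events = []
    for onset, duration, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        kind = desc.strip()
        kind = kind.lower() if kind.lower() in _EDF_EVENT_KINDS else kind
        if kind == "rera":
            kind = "RERA"
        if duration <= 0:
            duration = 1.0 / fs  # instantaneous markers get one sample
        events.append(EventAnnotation(kind=kind, start=float(onset), duration=float(duration)))
    return NasalPressureRecord(
        times=times, pressure=data, sampling_rate=fs, annotations=tuple(events)
    )


def load_config(path: str | Path) -> dict:
    """YAML or JSON document -> dict (empty file -> empty dict)."""
    path = Path(path)
    text = path.read_text()
    doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return doc


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> dict:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    import numpy
    import scipy

    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "versions": {
            "oxsa": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
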