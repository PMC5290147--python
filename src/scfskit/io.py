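"""Plain-text formats for curves, datasets, features and run configuration.

The curve dialect is a tab-separated file with ``# key: value`` header lines
followed by three columns (``segment``, ``height_m``, ``force_N``).  All
numeric values are written with ``repr`` so a write -> read round trip is
lossless to full float precision.  Files use SI units (m, N, s); reports
convert to nN / pN for display.  The vendor's proprietary instrument format
is deliberately not re-implemented; an adapter only needs to produce
:class:`~scfskit.processing.ForceCurve` objects to join the pipeline.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .processing import ForceCurve, Segment, CurveFeatures
from .stats import AdhesionDataset, DATASET_COLUMNS
from .synthetic import AcquisitionParams, ConditionSpec, SimulationConfig

__all__ = [
    "read_curve", "write_curve", "read_dataset", "write_dataset",
    "write_features", "read_features", "RunConfig", "load_run_config",
    "simulation_config_from_dict", "simulation_config_to_dict",
]

_MANDATORY_KEYS = (
    "curve_id", "cell_id", "condition", "contact_time_s",
    "spring_constant_N_per_m", "setpoint_N", "retract_speed_m_per_s",
)
_SEGMENT_ORDER = ("approach", "dwell", "retract")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_curve(curve: ForceCurve, path: str | Path) -> None:
    """Write a curve in the TSV dialect (losslessly re-readable)."""
    meta = curve.meta
    lines = [
        f"# curve_id: {curve.curve_id}",
        f"# cell_id: {curve.cell_id}",
        f"# condition: {curve.condition}",
        f"# contact_time_s: {_fmt(meta.get('contact_time_s', 0.0))}",
        f"# spring_constant_N_per_m: {_fmt(meta.get('spring_constant', 0.06))}",
        f"# setpoint_N: {_fmt(meta.get('setpoint_force', 0.0))}",
        f"# retract_speed_m_per_s: {_fmt(meta.get('retract_speed', 0.0))}",
        "segment\theight_m\tforce_N",
    ]
    for name in _SEGMENT_ORDER:
        if name not in curve.segments:
            continue
        h, f = curve.segments[name]
        for hv, fv in zip(h, f):
            lines.append(f"{name}\t{_fmt(hv)}\t{_fmt(fv)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> ForceCurve:
    """Read a curve from the TSV dialect; tolerant to CRLF line endings."""
    text = Path(path).read_text()
    header: dict[str, str] = {}
    segments: dict[str, tuple[list[float], list[float]]] = {}
    saw_columns = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
            continue
        if not saw_columns:
            cols = line.split("\t")
            if cols[:3] != ["segment", "height_m", "force_N"]:
                raise ValueError(f"{path}: line {lineno}: expected column "
                                 "header 'segment\\theight_m\\tforce_N'")
            saw_columns = True
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}: line {lineno}: expected 3 columns")
        seg = parts[0]
        try:
            h, f = float(parts[1]), float(parts[2])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-numeric value")
        segments.setdefault(seg, ([], []))[0].append(h)
        segments[seg][1].append(f)

    for key in _MANDATORY_KEYS:
        if key not in header:
            raise ValueError(f"{path}: missing mandatory header key {key!r}")
    if "retract" not in segments:
        raise ValueError(f"{path}: no retract segment")
    meta = {
        "contact_time_s": float(header["contact_time_s"]),
        "spring_constant": float(header["spring_constant_N_per_m"]),
        "setpoint_force": float(header["setpoint_N"]),
        "retract_speed": float(header["retract_speed_m_per_s"]),
    }
    segs = {name: Segment(np.array(h), np.array(f))
            for name, (h, f) in segments.items()}
    return ForceCurve(curve_id=header["curve_id"], segments=segs, meta=meta,
                      condition=header["condition"], cell_id=header["cell_id"])


# ---------------------------------------------------------------------------
# tidy tables
# ---------------------------------------------------------------------------

def write_dataset(ds: AdhesionDataset | pd.DataFrame, path: str | Path) -> None:
    """Write the adhesion dataset CSV with full-precision floats."""
    df = ds.df if isinstance(ds, AdhesionDataset) else ds
    buf = _stdio.StringIO()
    buf.write(",".join(DATASET_COLUMNS) + "\n")
    for row in df.itertuples(index=False):
        buf.write(f"{row.cell_id},{row.condition},"
                  f"{_fmt(row.contact_time_s)},{_fmt(row.adhesion_force_N)}\n")
    Path(path).write_text(buf.getvalue())


def read_dataset(path: str | Path) -> AdhesionDataset:
    """Read the dataset CSV, validating the one-force-per-cell-per-time
    protocol (duplicate (cell, condition, time) rows are rejected)."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    key = ["cell_id", "condition", "contact_time_s"]
    dupes = df.duplicated(subset=key)
    if dupes.any():
        first = df.loc[dupes.idxmax(), key].tolist()
        raise ValueError(f"{path}: duplicate (cell, condition, time) rows, "
                         f"first at {first}")
    return AdhesionDataset(df[list(DATASET_COLUMNS)])


_FEATURE_COLUMNS = ("curve_id", "cell_id", "condition", "contact_time_s",
                    "adhesion_force_N", "n_events", "specific_binding",
                    "noise_sd_N")


def write_features(features: list[CurveFeatures], path: str | Path) -> None:
    rows = [(f.curve_id, f.cell_id, f.condition, f.contact_time_s,
             f.adhesion_force, len(f.events), f.specific_binding,
             f.noise_sd_robust) for f in features]
    df = pd.DataFrame(rows, columns=list(_FEATURE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _check_keys(mapping: Mapping[str, Any], allowed: tuple[str, ...],
                context: str) -> None:
    unknown = sorted(set(mapping) - set(allowed))
    if unknown:
        raise ValueError(f"{context}: unknown keys {unknown}; "
                         f"allowed keys are {sorted(allowed)}")


def simulation_config_from_dict(doc: Mapping[str, Any]) -> SimulationConfig:
    """Build a SimulationConfig from a YAML/JSON document, rejecting unknown
    keys with a message."""
    allowed = tuple(f.name for f in dataclasses.fields(SimulationConfig))
    _check_keys(doc, allowed, "simulation config")
    kwargs: dict[str, Any] = dict(doc)
    cond_fields = tuple(f.name for f in dataclasses.fields(ConditionSpec))
    conditions = []
    for cdoc in doc.get("conditions", ()):
        _check_keys(cdoc, cond_fields, f"condition {cdoc.get('name', '?')!r}")
        conditions.append(ConditionSpec(**cdoc))
    kwargs["conditions"] = tuple(conditions)
    if "acquisition" in doc:
        acq_fields = tuple(f.name for f in dataclasses.fields(AcquisitionParams))
        _check_keys(doc["acquisition"], acq_fields, "acquisition")
        kwargs["acquisition"] = AcquisitionParams(**doc["acquisition"])
    if "contact_times" in doc:
        kwargs["contact_times"] = tuple(float(t) for t in doc["contact_times"])
    return SimulationConfig(**kwargs)


def simulation_config_to_dict(config: SimulationConfig) -> dict[str, Any]:
    return {
        "conditions": [dataclasses.asdict(c) for c in config.conditions],
        "contact_times": list(config.contact_times),
        "n_cells": config.n_cells,
        "curves_per_cell_per_time": config.curves_per_cell_per_time,
        "acquisition": dataclasses.asdict(config.acquisition),
        "seed": config.seed,
    }


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Schema-validated configuration for a full pipeline run."""

    simulation: SimulationConfig
    tail_fraction: float = 0.30
    k_sigma: float = 5.0
    B: int = 100
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "scfs-run"

    def __post_init__(self) -> None:
        if not 0 < self.tail_fraction < 1:
            raise ValueError("tail_fraction must be in (0, 1)")
        if self.k_sigma <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("k_sigma must be > 0 and alpha in (0, 1)")


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, Mapping):
        raise ValueError(f"{path}: expected a mapping at top level")
    allowed = tuple(f.name for f in dataclasses.fields(RunConfig))
    _check_keys(doc, allowed, str(path))
    kwargs: dict[str, Any] = dict(doc)
    if "simulation" not in doc:
        raise ValueError(f"{path}: missing 'simulation' section")
    kwargs["simulation"] = simulation_config_from_dict(doc["simulation"])
    return RunConfig(**kwargs)
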