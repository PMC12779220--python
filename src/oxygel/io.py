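"""Trace/result file handling, configuration parsing and settings hashing.

Probe traces travel as delimited text with ``#`` comment headers — the
shape of a typical optode logger export — described explicitly by a
:class:`TraceFileSpec` rather than guessing a fixed dialect.  Scalar
results are written as JSON with enough metadata (settings hash, package
version) to reproduce them; curves and profiles go to CSV with unit-bearing
headers.  Configuration is a single YAML file with flat key–value
sections (``constants``, ``geometry``, ``solver``, ``fit``, ``slab``,
``synth``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import MOL_PER_M3, UNITS
from .design import DesignCurve, DimensionlessReport
from .fitting import DiffusionFitResult
from .reaction import SteadyProfile
from .transient import ProbeTrace

__all__ = [
    "TraceFileSpec",
    "read_trace",
    "write_trace",
    "write_results",
    "settings_hash",
    "load_config",
]

_META_PREFIX = "meta:"


@dataclass(frozen=True)
class TraceFileSpec:
    """How to interpret a delimited trace file."""

    delimiter: str = ","
    comment: str = "#"
    time_col: str | int = "time_s"
    time_unit: str = "s"  # "s" or "min"
    oxygen_col: str | int = "oxygen"
    oxygen_unit: str = MOL_PER_M3
    decimal: str = "."

    def __post_init__(self) -> None:
        if self.time_col == self.oxygen_col:
            raise ValueError("time and oxygen columns must be distinct")
        if self.time_unit not in ("s", "min"):
            raise ValueError("time unit must be 's' or 'min'")
        if self.oxygen_unit not in UNITS:
            raise ValueError(f"oxygen unit must be one of {sorted(UNITS)}")


def read_trace(path, spec: TraceFileSpec | None = None) -> ProbeTrace:
    """Read a delimited trace file into a :class:`ProbeTrace`.

    Times are converted to seconds.  Non-monotone or duplicated
    timestamps are rejected with the offending data row named, never
    silently sorted.  Comment lines are preserved in the metadata; a
    ``# meta: {...}`` line (as written by :func:`write_trace`)
    round-trips structured metadata.
    """
    spec = spec or TraceFileSpec()
    path = Path(path)
    comments: list[str] = []
    metadata: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith(spec.comment):
                break
            body = line[len(spec.comment) :].strip()
            if body.startswith(_META_PREFIX):
                try:
                    metadata.update(json.loads(body[len(_META_PREFIX) :]))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}: malformed metadata line: {exc}") from exc
            elif body:
                comments.append(body)
    header = None if isinstance(spec.time_col, int) else 0
    try:
        df = pd.read_csv(
            path,
            sep=spec.delimiter,
            comment=spec.comment,
            decimal=spec.decimal,
            header=header,
        )
    except Exception as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    oxygen_col, oxygen_unit = spec.oxygen_col, spec.oxygen_unit
    if isinstance(oxygen_col, str) and oxygen_col == "oxygen" and oxygen_col not in df.columns:
        # unit-suffixed header written by write_trace, e.g. "oxygen_mol_per_m3"
        cands = [c for c in df.columns if str(c).startswith("oxygen")]
        if len(cands) == 1:
            oxygen_col = str(cands[0])
            suffix = oxygen_col[len("oxygen_") :] if oxygen_col.startswith("oxygen_") else ""
            if suffix in UNITS:
                oxygen_unit = suffix
    for col in (spec.time_col, oxygen_col):
        if (isinstance(col, int) and col >= df.shape[1]) or (
            isinstance(col, str) and col not in df.columns
        ):
            raise ValueError(f"{path}: missing column {col!r} (found {list(df.columns)})")
    def take(c):
        return df.iloc[:, c] if isinstance(c, int) else df[c]
    times = pd.to_numeric(take(spec.time_col), errors="coerce").to_numpy(dtype=float)
    values = pd.to_numeric(take(oxygen_col), errors="coerce").to_numpy(dtype=float)
    for name, arr in (("time", times), ("oxygen", values)):
        bad = np.nonzero(~np.isfinite(arr))[0]
        if bad.size:
            raise ValueError(f"{path}: unparseable {name} value at data row {bad[0] + 1}")
    if spec.time_unit == "min":
        times = times * 60.0
    dt = np.diff(times)
    viol = np.nonzero(dt <= 0)[0]
    if viol.size:
        row = viol[0] + 2  # 1-based, row after the first of the pair
        kind = "duplicated" if dt[viol[0]] == 0 else "decreasing"
        raise ValueError(f"{path}: {kind} timestamp at data row {row}")
    if comments:
        metadata.setdefault("comments", comments)
    return ProbeTrace(times, values, unit=oxygen_unit, metadata=metadata)


def write_trace(trace: ProbeTrace, path, spec: TraceFileSpec | None = None) -> None:
    """Write a trace as two-column delimited text with a metadata header."""
    spec = spec or TraceFileSpec(oxygen_unit=trace.unit)
    path = Path(path)
    with open(path, "w") as fh:
        if trace.metadata:
            fh.write(
                f"{spec.comment} {_META_PREFIX} "
                f"{json.dumps(trace.metadata, sort_keys=True, default=str)}\n"
            )
        fh.write(f"time_s{spec.delimiter}oxygen_{trace.unit}\n")
        for t, v in zip(trace.times_s, trace.values):
            fh.write(f"{float(t)!r}{spec.delimiter}{float(v)!r}\n")


def settings_hash(settings: dict) -> str:
    """Short stable hash of a canonicalized settings mapping."""
    canon = json.dumps(settings, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _result_envelope(settings: dict) -> dict:
    return {"settings": settings, "settings_hash": settings_hash(settings), "version": __version__}


def write_results(result, path) -> None:
    """Serialize a result object: JSON for scalar reports, CSV for curves.

    Supports :class:`DiffusionFitResult` and :class:`DimensionlessReport`
    (JSON) and :class:`DesignCurve` / :class:`SteadyProfile` (CSV with a
    unit-bearing header and a JSON sidecar comment line).
    """
    path = Path(path)
    if isinstance(result, DiffusionFitResult):
        payload = {
            "D_hat_cm2_s": result.D_hat_cm2_s,
            "mape_pct": result.mape_pct,
            "iterations": result.iterations,
            "converged": result.converged,
            "window_s": list(result.window_s),
            **_result_envelope(result.settings),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif isinstance(result, DimensionlessReport):
        payload = {**result.to_dict(), **_result_envelope(result.inputs)}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif isinstance(result, DesignCurve):
        df = pd.DataFrame(
            {
                "cells_per_mL": result.cells_per_mL,
                "X": result.X,
                "C_s_mol_m3": result.C_s_mol_m3,
                "phi": result.phi,
                "eta": result.eta,
                "L_mm": result.L_mm,
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# meta: {json.dumps(_result_envelope(result.params))}\n")
            df.to_csv(fh, index=False)
    elif isinstance(result, SteadyProfile):
        df = pd.DataFrame({"depth_mm": result.depth_mm, "C_mol_m3": result.C_mol_m3})
        env = _result_envelope(
            {**result.params, "x_v_mm": result.x_v_mm, "eta": result.eta, "status": result.status}
        )
        with open(path, "w") as fh:
            fh.write(f"# meta: {json.dumps(env)}\n")
            df.to_csv(fh, index=False)
    else:
        raise TypeError(f"don't know how to serialize {type(result).__name__}")


def load_config(path) -> dict:
    """Load the sectioned YAML configuration file as a nested dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration root in {path} must be a mapping")
    return cfg
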