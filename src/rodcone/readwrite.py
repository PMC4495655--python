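"""Reading and writing traces, filters, and fitted models.

Traces travel as two-column CSV (``time_s,value``) with an optional JSON
metadata sidecar (``<path>.meta.json``) recording units, dt, and generator
parameters.  Filters and nonlinearities serialize to JSON.
"""
from __future__ import annotations

import csv
import json
import os
from typing import Any

import numpy as np

from .core import LinearFilter, ParameterError, Trace
from .ln import LNModel
from .nonlinearities import Nonlinearity, nonlinearity_from_dict

__all__ = [
    "write_trace",
    "read_trace",
    "filter_to_dict",
    "filter_from_dict",
    "write_model",
    "read_model",
]

_REL_TOL = 1e-9  # relative tolerance on time-grid uniformity


def _sidecar(path: str) -> str:
    return str(path) + ".meta.json"


def write_trace(trace: Trace, path: str,
                metadata: dict[str, Any] | None = None) -> None:
    """Write a trace as CSV plus a JSON metadata sidecar.

    Values are written with full float64 round-trip precision.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "value"])
        for t, v in zip(trace.times, trace.values):
            writer.writerow([repr(float(t)), repr(float(v))])
    meta = {"units": trace.units, "dt": trace.dt,
            "start_time": trace.start_time}
    if metadata:
        meta.update(metadata)
    with open(_sidecar(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_trace(path: str) -> Trace:
    """Read a trace CSV, validating the header and time-grid uniformity."""
    times: list[float] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParameterError(f"{path}: empty file")
        if [h.strip() for h in header] != ["time_s", "value"]:
            raise ParameterError(
                f"{path}: expected header 'time_s,value', got {header}")
        for row_num, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ParameterError(
                    f"{path}: row {row_num} has {len(row)} fields, expected 2")
            try:
                times.append(float(row[0]))
                values.append(float(row[1]))
            except ValueError:
                raise ParameterError(
                    f"{path}: row {row_num} is not numeric: {row}")
    if not values:
        raise ParameterError(f"{path}: no data rows")

    units, dt, start = "a.u.", None, times[0]
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
        units = meta.get("units", units)
        dt = meta.get("dt")
    if len(times) > 1:
        diffs = np.diff(times)
        grid_dt = diffs[0] if dt is None else dt
        bad = np.nonzero(np.abs(diffs - grid_dt) > _REL_TOL * max(abs(grid_dt), 1e-300))[0]
        if bad.size:
            raise ParameterError(
                f"{path}: non-uniform time grid at row {int(bad[0]) + 3} "
                f"(spacing {diffs[bad[0]]:.12g}, expected {grid_dt:.12g})")
        dt = float(grid_dt)
    elif dt is None:
        raise ParameterError(
            f"{path}: single-row trace needs a dt in its metadata sidecar")
    return Trace(np.asarray(values), dt, start_time=start, units=units)


def filter_to_dict(filt: LinearFilter) -> dict[str, Any]:
    return {"dt": filt.dt, "taps": filt.taps.tolist(), "pathway": filt.pathway}


def filter_from_dict(d: dict[str, Any]) -> LinearFilter:
    return LinearFilter(d["dt"], np.asarray(d["taps"]), d.get("pathway"))


def write_model(model: LNModel, path: str,
                metadata: dict[str, Any] | None = None) -> None:
    """Serialize a fitted LN model (filter taps + nonlinearity) to JSON."""
    doc = {"dt": model.dt,
           "filter": filter_to_dict(model.filter),
           "nonlinearity": model.nonlinearity.to_dict()}
    if metadata:
        doc["metadata"] = metadata
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path: str) -> LNModel:
    with open(path) as fh:
        doc = json.load(fh)
    filt = filter_from_dict(doc["filter"])
    nonlin: Nonlinearity = nonlinearity_from_dict(doc["nonlinearity"])
    return LNModel(filter=filt, nonlinearity=nonlin, dt=doc["dt"])
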