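"""Plain-text persistence: two-column CSVs with JSON sidecars.

Traces are written as CSV (time_s, position_bp) plus ``<name>.json`` holding
the variant, seed and ground-truth event log; chase series and triplex curves
as (time, value) CSVs with parameter sidecars.  Everything round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path as _P

import numpy as np
import pandas as pd

from .simulate import ChaseSeries, Trace, TriplexCurve


def _sidecar(path) -> _P:
    p = _P(path)
    return p.with_suffix(p.suffix + ".json")


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "position_bp": trace.position_bp}).to_csv(
        path, index=False
    )
    meta = {"variant": trace.variant, "seed": trace.seed, "events": _jsonable(trace.events)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace_csv(path) -> Trace:
    df = pd.read_csv(path)
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return Trace(
        time_s=df["time_s"].to_numpy(),
        position_bp=df["position_bp"].to_numpy(),
        events=meta.get("events", {}),
        variant=meta.get("variant", ""),
        seed=meta.get("seed"),
    )


def write_chase_csv(series: ChaseSeries, path) -> None:
    pd.DataFrame(
        {"time_min": series.time_min, "fragment_fraction": series.fragment_fraction}
    ).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps({"n_molecules": series.n_molecules}))


def read_chase_csv(path) -> ChaseSeries:
    df = pd.read_csv(path)
    n = 0
    side = _sidecar(path)
    if side.exists():
        n = json.loads(side.read_text()).get("n_molecules", 0)
    return ChaseSeries(
        time_min=df.iloc[:, 0].to_numpy(),
        fragment_fraction=df.iloc[:, 1].to_numpy(),
        n_molecules=n,
    )


def write_triplex_csv(curve: TriplexCurve, path) -> None:
    pd.DataFrame({"time_s": curve.time_s, "signal": curve.signal}).to_csv(
        path, index=False
    )
    meta = {
        "n_chi": curve.n_chi,
        "triplex_distance_bp": curve.triplex_distance_bp,
        "n_molecules": curve.n_molecules,
        "n_reported": curve.n_reported,
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_triplex_csv(path) -> TriplexCurve:
    df = pd.read_csv(path)
    meta = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return TriplexCurve(
        time_s=df.iloc[:, 0].to_numpy(),
        signal=df.iloc[:, 1].to_numpy(),
        n_chi=meta.get("n_chi", 0),
        triplex_distance_bp=meta.get("triplex_distance_bp", float("nan")),
        n_molecules=meta.get("n_molecules", 0),
        n_reported=meta.get("n_reported", 0),
    )
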