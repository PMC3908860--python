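"""Serialization: trace CSV, stats JSON, regime-grid TSV, config files.

Floating-point text output uses 12 significant digits throughout, which
round-trips times and voltages to well below every tolerance used in the
analysis (the bifurcation anchors need 10 digits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import TemporalStats, WaveStats
from .model import NeuronParams, TauRule
from .regimes import CoregulationPath, FitResult, RegimeGrid
from .simulate import Trace

__all__ = [
    "write_trace",
    "read_trace",
    "write_stats",
    "read_stats",
    "write_grid",
    "read_grid",
    "write_fit",
    "read_fit",
    "write_path",
    "load_params",
    "dump_params",
]

FLOAT_FMT = "%.12g"


def write_trace(trace: Trace, path) -> None:
    """Trace as CSV (t plus one column block per cell) with a JSON sidecar
    for metadata and event-detected spike times."""
    path = Path(path)
    df = pd.DataFrame(trace.states, columns=trace.columns)
    df.insert(0, "t", trace.times)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "n_cells": trace.n_cells,
        "spikes": [list(map(float, s)) for s in trace.spikes],
        "metadata": {k: v for k, v in trace.metadata.items() if _jsonable(v)},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_trace(path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    n_cells, spikes, metadata = 1, [], {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        n_cells = meta.get("n_cells", 1)
        spikes = [np.asarray(s) for s in meta.get("spikes", [])]
        metadata = meta.get("metadata", {})
    return Trace(
        times=df["t"].to_numpy(),
        states=df.drop(columns="t").to_numpy(),
        n_cells=n_cells,
        spikes=spikes,
        metadata=metadata,
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _round12(x: float) -> float:
    return float(FLOAT_FMT % x)


def write_stats(stats, path) -> None:
    """TemporalStats or WaveStats as JSON."""
    d = dataclasses.asdict(stats)
    d["__type__"] = type(stats).__name__
    out = {
        k: ([_round12(x) for x in v] if isinstance(v, np.ndarray) else v)
        for k, v in d.items()
    }
    Path(path).write_text(json.dumps(out, indent=1))


def read_stats(path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("__type__")
    cls = {"TemporalStats": TemporalStats, "WaveStats": WaveStats}[kind]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {
        k: (np.asarray(v) if isinstance(v, list) else v)
        for k, v in d.items()
        if k in fields
    }
    return cls(**kwargs)


def write_grid(grid: RegimeGrid, path) -> None:
    """Regime grid as long-format TSV (theta_k2, theta_h, label, duty)."""
    rows = []
    for i, tk in enumerate(grid.theta_k2_axis):
        for j, th in enumerate(grid.theta_h_axis):
            d = grid.duty[i, j]
            rows.append((tk, th, grid.labels[i, j], "" if np.isnan(d) else FLOAT_FMT % d))
    df = pd.DataFrame(rows, columns=["theta_k2", "theta_h", "label", "duty"])
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_grid(path) -> RegimeGrid:
    df = pd.read_csv(path, sep="\t")
    tk = np.unique(df["theta_k2"].to_numpy())
    th = np.unique(df["theta_h"].to_numpy())
    labels = np.empty((tk.size, th.size), dtype=object)
    duty = np.full((tk.size, th.size), np.nan)
    for _, r in df.iterrows():
        i = int(np.searchsorted(tk, r["theta_k2"]))
        j = int(np.searchsorted(th, r["theta_h"]))
        labels[i, j] = r["label"]
        if not pd.isna(r["duty"]):
            duty[i, j] = float(r["duty"])
    return RegimeGrid(tk, th, labels, duty)


def write_fit(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(fit), indent=1))


def read_fit(path) -> FitResult:
    return FitResult(**json.loads(Path(path).read_text()))


def write_path(cp: CoregulationPath, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(cp), indent=1))


# --------------------------------------------------------------------------
# parameter configuration files
# --------------------------------------------------------------------------

def dump_params(params: NeuronParams, path) -> None:
    """Flat YAML of every cell parameter (TauRule expanded inline)."""
    d = dataclasses.asdict(params)
    d["tau_mh"] = dataclasses.asdict(params.tau_mh)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_params(path=None, **overrides) -> NeuronParams:
    """NeuronParams from a YAML file (defaults when ``path`` is None),
    with keyword overrides applied on top."""
    if path is None:
        d = {}
    else:
        d = yaml.safe_load(Path(path).read_text()) or {}
    if isinstance(d.get("tau_mh"), dict):
        d["tau_mh"] = TauRule(**d["tau_mh"])
    d.update(overrides)
    return NeuronParams(**d)
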