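"""Trace and config I/O: tidy CSV traces with a JSON metadata sidecar.

Trace format: a flat CSV (one row per saved step; column order fixed by the
writer: t, the seven state variables, the synapse variables x/y/g, the
derived extracellular concentrations and the flux breakdown) plus
``<path>.meta.json`` carrying the full run manifest — parameters, geometry,
protocol, seed, dt, calibration report and code version — so a run can be
reproduced bit-identically from the sidecar alone.

Config format: a flat YAML mapping.  Keys are ModelParameters field names
plus the reserved run keys below; unknown keys are rejected by name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .engine import SimulationTrace
from .parameters import ModelParameters, load_parameters

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: run-level config keys that are not ModelParameters fields
RUN_KEYS = frozenset({
    "svr", "ratio_er", "stim", "rate", "duration", "glutamate", "seed",
    "spike_file", "dt", "save_every", "calibration", "mglur_only",
    "block_glut", "er_free",
})


def write_trace(trace: SimulationTrace, path: str | Path) -> None:
    path = Path(path)
    trace.data.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    payload = {"schema_version": SCHEMA_VERSION, **trace.metadata}
    sidecar.write_text(json.dumps(payload, indent=2, default=float))


def read_trace(path: str | Path) -> SimulationTrace:
    path = Path(path)
    data = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
        version = metadata.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValueError(f"trace schema version {version!r} not supported "
                             f"(expected {SCHEMA_VERSION})")
    else:
        log.warning("no metadata sidecar for %s; best-effort load", path)
        metadata = {}
    return SimulationTrace(data=data, metadata=metadata)


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a flat YAML config; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError(f"config {path} must be a flat mapping")
    return dict(cfg)


def split_config(cfg: Mapping[str, Any]) -> tuple[ModelParameters, dict[str, Any]]:
    """Split a flat config into a validated parameter set and run options."""
    run = {k: v for k, v in cfg.items() if k in RUN_KEYS}
    model = {k: v for k, v in cfg.items() if k not in RUN_KEYS}
    return load_parameters(model), run
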