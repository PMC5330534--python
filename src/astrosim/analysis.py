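"""Summary quantities extracted from simulation traces.

Oscillation detection works on the cytosolic Ca2+ trace by prominence-based
peak counting (no spectral estimate): after discarding a settle window, the
trace oscillates if it shows at least two prominent peaks and two prominent
troughs whose mean peak-to-trough excursion exceeds ``amp_min``.  The
frequency is the peak count divided by the analyzed duration, matching how
limit-cycle frequencies are usually read off such simulations.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .engine import SimulationTrace, simulate
from .geometry import CompartmentGeometry
from .parameters import ModelParameters, default_parameters
from .stimulus import StimulusProtocol

log = logging.getLogger(__name__)

#: default peak-to-trough amplitude (µM) below which Ca_i activity is not
#: counted as an oscillation, and default settle window (s) discarded before
#: analysis.  Exposed as keyword arguments everywhere they are used.
AMP_MIN = 0.05
SETTLE = 20.0


def _ca_series(trace) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(trace, SimulationTrace):
        return trace.t, trace["Ca_i"]
    if isinstance(trace, pd.DataFrame):
        return trace["t"].to_numpy(), trace["Ca_i"].to_numpy()
    t, ca = trace
    return np.asarray(t, dtype=float), np.asarray(ca, dtype=float)


@dataclass
class OscillationSummary:
    oscillating: bool
    frequency: float            # Hz; 0 when not oscillating
    mean_peak: float            # µM
    mean_trough: float          # µM
    n_cycles: int
    mean_Ca: float              # µM average over the analyzed window

    def to_dict(self) -> dict[str, Any]:
        return {"oscillating": self.oscillating, "frequency": self.frequency,
                "mean_peak": self.mean_peak, "mean_trough": self.mean_trough,
                "n_cycles": self.n_cycles, "mean_Ca": self.mean_Ca}


def detect_oscillations(trace, settle: float = SETTLE,
                        amp_min: float = AMP_MIN) -> OscillationSummary:
    """Classify the Ca_i trace after ``settle`` seconds as oscillating or not.

    Oscillating requires >= 2 prominent peaks and troughs (prominence
    ``amp_min``) with a mean peak-to-trough excursion >= ``amp_min``.
    Frequency is n_cycles (peak count) / analyzed duration, so it is
    invariant under time reversal of the trace.
    """
    t, ca = _ca_series(trace)
    if t[-1] - t[0] <= settle:
        raise ValueError(f"trace duration {t[-1] - t[0]:.3g} s does not "
                         f"exceed the settle window ({settle:.3g} s)")
    keep = t >= t[0] + settle
    t, ca = t[keep], ca[keep]
    duration = t[-1] - t[0]
    peaks, _ = find_peaks(ca, prominence=amp_min)
    troughs, _ = find_peaks(-ca, prominence=amp_min)
    mean_ca = float(np.mean(ca))
    if len(peaks) >= 2 and len(troughs) >= 2:
        mean_peak = float(np.mean(ca[peaks]))
        mean_trough = float(np.mean(ca[troughs]))
        if mean_peak - mean_trough >= amp_min:
            n = len(peaks)
            return OscillationSummary(True, n / duration, mean_peak,
                                      mean_trough, n, mean_ca)
    return OscillationSummary(False, 0.0, mean_ca, mean_ca, 0, mean_ca)


def na_saturation(trace, epsilon: float = 0.01,
                  na_rest: float | None = None) -> tuple[float, float]:
    """(delta_Na [mM], t_sat [s]) of the intracellular Na+ trace.

    delta_Na is the final minus the resting concentration; t_sat is the
    first time after which Na_i stays within ``epsilon`` of |delta_Na| of
    its final value for the remainder of the run (0 for a flat trace).
    """
    if isinstance(trace, SimulationTrace):
        t, na = trace.t, trace["Na_i"]
        if na_rest is None:
            na_rest = trace.metadata["parameters"]["Na_i_rest"]
    elif isinstance(trace, pd.DataFrame):
        t, na = trace["t"].to_numpy(), trace["Na_i"].to_numpy()
    else:
        t, na = (np.asarray(a, dtype=float) for a in trace)
    if na_rest is None:
        na_rest = na[0]
    delta = float(na[-1] - na_rest)
    band = epsilon * abs(delta)
    dev = np.abs(na - na[-1])
    outside = np.nonzero(dev > band)[0]
    t_sat = 0.0 if outside.size == 0 else float(t[min(outside[-1] + 1,
                                                      len(t) - 1)])
    return delta, t_sat


def block_reduction(control, blocked, rest_ca: float) -> float:
    """Percent attenuation of the stimulus-evoked Ca signal under block.

    100 * (mean(Ca_ctrl) - mean(Ca_block)) / (mean(Ca_ctrl) - rest_ca).
    NaN if the control signal does not rise above rest (undefined ratio).
    """
    _, ca_c = _ca_series(control)
    _, ca_b = _ca_series(blocked)
    denom = float(np.mean(ca_c)) - rest_ca
    if abs(denom) <= 1e-12 * max(1.0, abs(rest_ca)):
        log.warning("block_reduction undefined: control mean equals rest")
        return float("nan")
    return 100.0 * (float(np.mean(ca_c)) - float(np.mean(ca_b))) / denom


def critical_ratio_er(params: ModelParameters | None = None,
                      protocol: StimulusProtocol | None = None,
                      grid: Sequence[float] | None = None,
                      seeds: Sequence[int] = (0, 1, 2, 3, 4),
                      svr: float = 1.0,
                      dt: float = 1e-3,
                      save_every: int = 20,
                      settle: float = SETTLE,
                      amp_min: float = AMP_MIN,
                      store_init: str = "balanced") -> float | None:
    """Onset of mGluR-driven Ca2+ oscillations along the store-size axis.

    Runs the store-release pathway in isolation (transmembrane currents
    silenced) for every ``ratio_er`` on the ascending grid and every seed of
    the Poisson stimulus, and returns the smallest ratio_er at which a
    majority of replicates oscillates (None if none does).

    In this subsystem total Ca2+ (cytosol + store) is conserved, so the
    onset also depends on the initial store load (``store_init``); the
    default is the self-consistent (flux-balanced) load, the only choice
    under which the rest state is stationary.  See docs/methods.md for how
    the onset value compares with the published one under either load.
    """
    p = default_parameters() if params is None else params
    if protocol is None:
        protocol = StimulusProtocol(mode="poisson", rate=100.0, duration=200.0)
    if grid is None:
        grid = np.round(np.arange(0.0, 0.1501, 0.01), 4)
    grid = sorted(float(r) for r in grid)
    seeds = [int(s) for s in seeds]
    for r in grid:
        votes = 0
        for seed in seeds:
            proto = StimulusProtocol(mode=protocol.mode, rate=protocol.rate,
                                     duration=protocol.duration,
                                     glutamate_level=protocol.glutamate_level,
                                     spike_times=protocol.spike_times,
                                     seed=int(seed))
            trace = simulate(proto, params=p,
                             geometry=CompartmentGeometry(svr=svr, ratio_er=r),
                             dt=dt, save_every=save_every, mglur_only=True,
                             store_init=store_init, record_fluxes=False)
            if detect_oscillations(trace, settle=settle,
                                   amp_min=amp_min).oscillating:
                votes += 1
        if votes > len(seeds) / 2:
            return r
    log.info("critical_ratio_er: no onset in grid %s", grid)
    return None


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Tidy per-cell records of a parameter sweep plus its generating spec."""

    table: pd.DataFrame
    axes: dict[str, list[float]]
    seeds: list[int]
    metadata: dict[str, Any] = field(default_factory=dict)


def _config_hash(payload: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=float).encode()
    ).hexdigest()[:16]


def run_sweep(axes: Mapping[str, Iterable[float]],
              metric: Callable[[SimulationTrace], Mapping[str, float]],
              params: ModelParameters | None = None,
              protocol: StimulusProtocol | None = None,
              seeds: Sequence[int] = (0,),
              svr: float = 1.0,
              dt: float = 1e-3,
              save_every: int = 20,
              cache: dict | None = None,
              **simulate_kwargs) -> SweepResult:
    """Grid sweep: one simulation + metric evaluation per cell per seed.

    ``axes`` maps parameter names (any ModelParameters field, or
    ``ratio_er``/``svr``) to value grids.  Cell failures are recorded
    (``error`` column) and the sweep continues.  An optional ``cache`` dict
    keyed by config hash makes repeated/resumed sweeps cheap.
    """
    p0 = default_parameters() if params is None else params
    if protocol is None:
        protocol = StimulusProtocol(mode="poisson", rate=100.0, duration=200.0)
    axes = {k: [float(v) for v in vals] for k, vals in axes.items()}
    records = []
    for combo in itertools.product(*axes.values()):
        cell = dict(zip(axes.keys(), combo))
        for seed in seeds:
            key = _config_hash({**cell, "seed": seed, "dt": dt,
                                "proto": protocol.mode, "rate": protocol.rate,
                                "duration": protocol.duration,
                                **simulate_kwargs})
            if cache is not None and key in cache:
                records.append(cache[key])
                continue
            overrides = dict(cell)
            geom = CompartmentGeometry(
                svr=overrides.pop("svr", svr),
                ratio_er=overrides.pop("ratio_er", None))
            try:
                p = p0.replace(**overrides) if overrides else p0
                proto = StimulusProtocol(
                    mode=protocol.mode, rate=protocol.rate,
                    duration=protocol.duration,
                    glutamate_level=protocol.glutamate_level,
                    spike_times=protocol.spike_times, seed=int(seed))
                trace = simulate(proto, params=p, geometry=geom, dt=dt,
                                 save_every=save_every, **simulate_kwargs)
                rec = {**cell, "seed": int(seed), "error": "",
                       **dict(metric(trace))}
            except Exception as exc:   # record and continue
                log.warning("sweep cell %s seed %s failed: %s", cell, seed, exc)
                rec = {**cell, "seed": int(seed), "error": str(exc)}
            records.append(rec)
            if cache is not None:
                cache[key] = rec
    table = pd.DataFrame.from_records(records)
    meta = {"protocol": protocol.mode, "rate": protocol.rate,
            "duration": protocol.duration, "dt": dt, "svr": svr,
            "simulate_kwargs": dict(simulate_kwargs)}
    return SweepResult(table=table, axes=axes, seeds=[int(s) for s in seeds],
                       metadata=meta)
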