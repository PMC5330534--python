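"""Extracellular glutamate protocols.

Spike-driven protocols convert a presynaptic spike train into a cleft
glutamate time course with the Tsodyks-Markram short-term-plasticity model:
x is the recovered vesicle fraction, y the utilization (active) fraction and
g the cleft glutamate concentration (µM).  Between spikes the three
variables relax exponentially; the delta-function spike terms of the model
are applied as discrete impulse updates at grid-snapped spike times, with
the standard ordering: facilitation first (y += U_0 (1 - y)), then release
using the post-update y (r = x y; x -= r; g += rho_C G_T r).

A single numpy Generator seeded from the protocol drives all randomness;
identical protocols produce bit-identical traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .parameters import ModelParameters

log = logging.getLogger(__name__)

MODES = ("poisson", "constant", "spike_list", "none")


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of one stimulation run.

    mode 'poisson': homogeneous Poisson train at ``rate`` Hz for ``duration`` s.
    mode 'constant': flat extracellular glutamate at ``glutamate_level`` µM.
    mode 'spike_list': explicit spike times (s), sorted, within [0, duration].
    mode 'none': no stimulation.
    """

    mode: str = "none"
    duration: float = 200.0
    rate: float = 0.0
    glutamate_level: float = 0.0
    spike_times: tuple[float, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.glutamate_level < 0:
            raise ValueError("glutamate_level must be >= 0")
        st = tuple(float(t) for t in self.spike_times)
        if any(b < a for a, b in zip(st, st[1:])):
            raise ValueError("spike_times must be sorted")
        if st and (st[0] < 0 or st[-1] > self.duration):
            raise ValueError("spike_times must lie within [0, duration]")
        object.__setattr__(self, "spike_times", st)


@dataclass
class SynapseState:
    """Tsodyks-Markram state: x, y in [0,1]; g >= 0 (µM). Rest is (1, 0, 0)."""

    x: float = 1.0
    y: float = 0.0
    g: float = 0.0


def poisson_spikes(rate: float, duration: float, seed: int) -> np.ndarray:
    """Sorted spike times of a homogeneous Poisson process, reproducible."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def tm_step(state: SynapseState, dt: float, spike: bool,
            p: ModelParameters) -> SynapseState:
    """One grid step of the synapse model (impulse first, then relaxation)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    tau_facil, tau_rec, tau_clear = p.tm_time_constants()
    x, y, g = state.x, state.y, state.g
    if spike:
        y += p.U_0 * (1.0 - y)
        r = x * y
        x -= r
        g += p.rho_C * p.G_T * r
    x += dt * (1.0 - x) / tau_rec
    y -= dt * y / tau_facil
    g -= dt * g / tau_clear
    return SynapseState(x=x, y=y, g=g)


@njit(cache=True)
def _tm_loop(spike_flags, dt, tau_facil, tau_rec, tau_clear, u0, rho_gt):
    n = spike_flags.size
    xs = np.empty(n)
    ys = np.empty(n)
    gs = np.empty(n)
    x, y, g = 1.0, 0.0, 0.0
    for k in range(n):
        if spike_flags[k]:
            y += u0 * (1.0 - y)
            r = x * y
            x -= r
            g += rho_gt * r
        xs[k] = x
        ys[k] = y
        gs[k] = g
        x += dt * (1.0 - x) / tau_rec
        y -= dt * y / tau_facil
        g -= dt * g / tau_clear
    return xs, ys, gs


def _spike_flags(times: np.ndarray, dt: float, n_steps: int) -> np.ndarray:
    """Snap spike times to the integration grid (nearest node).

    Two spikes landing in the same bin collapse to one; the collision count
    is logged.
    """
    flags = np.zeros(n_steps + 1, dtype=np.bool_)
    if times.size:
        idx = np.clip(np.rint(np.asarray(times) / dt).astype(np.int64), 0, n_steps)
        uniq = np.unique(idx)
        if uniq.size < idx.size:
            log.info("stimulus: %d spike(s) collided on the %g ms grid",
                     idx.size - uniq.size, dt * 1e3)
        flags[uniq] = True
    return flags


def glutamate_trace(protocol: StimulusProtocol, dt: float, p: ModelParameters,
                    n_steps: int | None = None):
    """Cleft glutamate (and synapse state) on the integration grid.

    Returns arrays (g, x, y) of length ``n_steps + 1`` with values at the
    grid nodes t_k = k*dt; the engine uses g[k] for the forward-Euler step
    from t_k to t_{k+1}.
    """
    if n_steps is None:
        n_steps = int(round(protocol.duration / dt))
    ones = np.ones(n_steps + 1)
    zeros = np.zeros(n_steps + 1)
    if protocol.mode == "none":
        return zeros, ones, zeros.copy()
    if protocol.mode == "constant":
        return protocol.glutamate_level * ones, ones, zeros
    if protocol.mode == "poisson":
        times = poisson_spikes(protocol.rate, protocol.duration, protocol.seed)
    else:
        times = np.asarray(protocol.spike_times, dtype=float)
    flags = _spike_flags(times, dt, n_steps)
    tau_facil, tau_rec, tau_clear = p.tm_time_constants()
    xs, ys, gs = _tm_loop(flags, dt, tau_facil, tau_rec, tau_clear,
                          p.U_0, p.rho_C * p.G_T)
    return gs, xs, ys
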