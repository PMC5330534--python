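"""Right-hand side assembly, resting-state calibration and Euler integration.

The dynamical state is

    y = (Ca_i [µM], Ca_ER [µM], Na_i [mM], K_i [mM], V [mV], IP3 [µM], h)

with the synapse variables (x, y, g) precomputed on the grid by the
stimulus module.  Extracellular Ca2+/Na+/K+ are algebraic mirror
constraints of the intracellular pools (equal intra/extracellular volumes,
fixed total content) evaluated from the state at every step — they are not
independent ODEs.  The balance equations are implemented verbatim from the
source model, including its sign conventions (positive I_NCX raises
cytosolic Ca2+) and the appearance of the ER currents in the voltage
equation.

There is exactly one RHS implementation: a numba kernel shared by the
public :func:`rhs`, the forward-Euler production integrator
(:func:`simulate`, the reference scheme, dt = 1 ms) and the adaptive
high-accuracy cross-check (:func:`integrate_reference`).

Calibration (:func:`calibrate_rest`) recomputes the resting IP3, h, ER Ca2+
and the two leak conductances from the stated zero-derivative conditions
instead of trusting the printed initial values, which are not mutually
consistent with the printed rate constants (see docs/methods.md).  With an
active Na+/Ca2+ exchanger the resting cytosolic Ca2+ is additionally placed
at the exchanger's reversal point (closed form), because the model has no
plasma-membrane Ca2+ leak that could cancel a finite resting NCX current;
this makes the calibrated rest an exact fixed point of the full system.
``calibration="printed"`` reproduces the published table values verbatim
for comparison runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Callable

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

from . import fluxes
from .geometry import CompartmentGeometry, membrane_rate_factor
from .parameters import ModelParameters, default_parameters
from .stimulus import StimulusProtocol, glutamate_trace

log = logging.getLogger(__name__)

STATE_NAMES = ("Ca_i", "Ca_ER", "Na_i", "K_i", "V", "IP3", "h")
FLUX_NAMES = ("J_IP3R", "J_Serca", "J_CERleak", "I_GluT", "I_NKA", "I_NCX",
              "I_Na_leak", "I_K_leak", "prod_PLCbeta", "prod_PLCdelta",
              "degr_IP3_3K", "degr_IP_5P")

_STATUS_MSG = {
    1: "extracellular concentration dropped to or below zero",
    2: "intracellular Na+ or K+ dropped to or below zero",
    3: "state became non-finite or exploded",
}


class SimulationError(RuntimeError):
    pass


class CalibrationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# parameter packing for the numba kernel
# --------------------------------------------------------------------------

_PV_FIELDS = (
    "v_beta", "K_R", "K_p", "K_pi", "v_delta", "kappa_delta", "K_PLCdelta",
    "v_3K", "K_D", "K_3", "r_5P",                       # 0-10  IP3 metabolism
    "r_C", "d1", "d5", "v_ER", "K_ER", "r_L", "a2", "d2", "d3",  # 11-19 ER
    "I_GluT_max", "K_GluT_mN", "K_GluT_mK", "K_GluT_mg",         # 20-23
    "I_NKA_max", "K_NKA_mN", "K_NKA_mK",                         # 24-26
    "I_NCX_max", "K_NCX_mN", "K_NCX_mC", "k_sat", "eta",         # 27-31
    "g_Na_leak", "g_K_leak",                                     # 32-33
)
# 34 rtf, 35 C_m, 36 Ca_i_rest, 37 Ca_ER_rest, 38 Ca_o_rest, 39 Na_i_rest,
# 40 Na_o_rest, 41 K_i_rest, 42 K_o_rest, 43 conv (µM/s per pA/µm²),
# 44 ratio_er, 45 ER-active flag
_PV_SIZE = 46


def _pack(p: ModelParameters, geom: CompartmentGeometry) -> np.ndarray:
    pv = np.empty(_PV_SIZE)
    for i, name in enumerate(_PV_FIELDS):
        pv[i] = getattr(p, name)
    pv[34] = p.rtf
    pv[35] = p.C_m
    pv[36] = p.Ca_i_rest
    pv[37] = p.Ca_ER_rest
    pv[38] = p.Ca_o_rest
    pv[39] = p.Na_i_rest
    pv[40] = p.Na_o_rest
    pv[41] = p.K_i_rest
    pv[42] = p.K_o_rest
    pv[43] = membrane_rate_factor(geom, p)
    pv[44] = geom.ratio_er
    pv[45] = 1.0 if geom.ratio_er > 0 else 0.0
    return pv


@njit(cache=True)
def _rhs_into(y, g, pv, dy):
    """Write d(state)/dt into ``dy``; return a nonzero status on bad state."""
    ca, caer, na, ki, v, ip3, h = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    # extracellular mirror constraints
    cao = pv[38] + (ca - pv[36]) + (pv[37] - caer)
    nao = pv[40] + (pv[39] - na)
    ko = pv[42] + (pv[41] - ki)
    if cao <= 0.0 or nao <= 0.0 or ko <= 0.0:
        return 1
    if na <= 0.0 or ki <= 0.0:
        return 2

    # ER fluxes as volumetric rates (µM/s); forced to zero without a store
    if pv[45] != 0.0:
        m = ip3 / (ip3 + pv[12])
        n = ca / (ca + pv[13])
        j_ip3r = pv[11] * (m * n * h) ** 3 * (caer - ca)
        j_serca = pv[14] * ca * ca / (ca * ca + pv[15] * pv[15])
        j_leak = pv[16] * (caer - ca)
        j_net = j_ip3r - j_serca + j_leak
    else:
        j_net = 0.0

    # plasma-membrane current densities (pA/µm²)
    na_o3 = nao * nao * nao
    i_glut = (pv[20] * ki / (ki + pv[22])
              * na_o3 / (na_o3 + pv[21] ** 3)
              * g / (g + pv[23]))
    na15 = na ** 1.5
    i_nka = pv[24] * na15 / (na15 + pv[25] ** 1.5) * ko / (ko + pv[26])
    rtf = pv[34]
    phi = v / rtf
    e_fwd = np.exp(pv[31] * phi)
    e_rev = np.exp((pv[31] - 1.0) * phi)
    pre = pv[27] * na_o3 / (pv[28] ** 3 + na_o3) * cao / (pv[29] + cao)
    i_ncx = (pre * ((na / nao) ** 3 * e_fwd - (ca / cao) * e_rev)
             / (1.0 + pv[30] * e_rev))
    i_na_leak = pv[32] * (v - rtf * np.log(nao / na))
    i_k_leak = pv[33] * (v - rtf * np.log(ko / ki))

    conv = pv[43]               # µM/s per pA/µm²; /1e3 for the mM species
    dy[0] = conv * i_ncx + pv[44] * j_net
    dy[1] = -j_net
    dy[2] = conv / 1e3 * (3.0 * i_glut - 3.0 * i_nka - 3.0 * i_ncx - i_na_leak)
    dy[3] = conv / 1e3 * (-i_glut + 2.0 * i_nka - i_k_leak)
    # voltage: ER currents re-expressed as densities through the same factor
    i_er = -2.0 * j_net / conv
    dy[4] = -(i_er + i_ncx - 2.0 * i_glut + i_nka + i_na_leak + i_k_leak) \
        / pv[35] * 1e3

    # IP3 metabolism
    mid = (pv[1] + pv[2] * ca / (ca + pv[3])) ** 0.7
    g07 = g ** 0.7 if g > 0.0 else 0.0
    prod_b = pv[0] * g07 / (g07 + mid)
    ca2 = ca * ca
    prod_d = pv[4] / (1.0 + ip3 / pv[5]) * ca2 / (ca2 + pv[6] * pv[6])
    ca4 = ca2 * ca2
    degr_3k = pv[7] * ca4 / (ca4 + pv[8] ** 4) * ip3 / (ip3 + pv[9])
    dy[5] = prod_b + prod_d - degr_3k - pv[10] * ip3

    # IP3R inactivation gate
    q2 = pv[18] * (ip3 + pv[12]) / (ip3 + pv[19])
    dy[6] = pv[17] * (q2 * (1.0 - h) - h * ca)
    return 0


@njit(cache=True)
def _euler_loop(y0, g_ext, dt, stride, pv):
    n_steps = g_ext.size - 1
    n_save = n_steps // stride + 1
    out = np.empty((n_save, 7))
    dy = np.empty(7)
    y = y0.copy()
    out[0] = y
    i_save = 1
    for k in range(n_steps):
        status = _rhs_into(y, g_ext[k], pv, dy)
        if status != 0:
            return out, status, k
        for j in range(7):
            y[j] += dt * dy[j]
        for j in range(7):
            if not np.isfinite(y[j]) or abs(y[j]) > 1e9:
                return out, 3, k
        if (k + 1) % stride == 0:
            out[i_save] = y
            i_save += 1
    return out, 0, n_steps


# --------------------------------------------------------------------------
# public RHS and extracellular constraints
# --------------------------------------------------------------------------

def rhs(state, g_ext: float, geom: CompartmentGeometry,
        p: ModelParameters) -> np.ndarray:
    """d(state)/dt for state (Ca_i, Ca_ER, Na_i, K_i, V, IP3, h).

    The extracellular anchors are taken from ``p`` (``Ca_i_rest`` etc.), so
    pass the calibrated parameter record when evaluating a calibrated run.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (7,):
        raise ValueError("state must have 7 components " + str(STATE_NAMES))
    dy = np.empty(7)
    status = _rhs_into(y, float(g_ext), _pack(p, geom), dy)
    if status != 0:
        raise SimulationError(_STATUS_MSG[status])
    return dy


def extracellular_state(state, p: ModelParameters) -> tuple[float, float, float]:
    """(Ca_o [µM], Na_o [mM], K_o [mM]) from the mirror constraints."""
    y = np.asarray(state, dtype=float)
    ca_o = p.Ca_o_rest + (y[0] - p.Ca_i_rest) + (p.Ca_ER_rest - y[1])
    na_o = p.Na_o_rest + (p.Na_i_rest - y[2])
    k_o = p.K_o_rest + (p.K_i_rest - y[3])
    if min(ca_o, na_o, k_o) <= 0:
        raise SimulationError(
            "extracellular concentration dropped to or below zero: "
            f"Ca_o={ca_o:.4g} µM, Na_o={na_o:.4g} mM, K_o={k_o:.4g} mM")
    return float(ca_o), float(na_o), float(k_o)


# --------------------------------------------------------------------------
# toggles and calibration
# --------------------------------------------------------------------------

def apply_toggles(p: ModelParameters, mglur_only: bool = False,
                  block_glut: bool = False) -> ModelParameters:
    """Pathway-block experiments expressed as parameter overrides.

    ``mglur_only`` silences the whole transmembrane pathway
    (I_GluT = I_NKA = I_NCX = 0); ``block_glut`` silences the glutamate
    transporter alone.  Leak conductances are recalibrated afterwards by
    :func:`calibrate_rest`, so every experiment starts at its own rest.
    """
    if mglur_only:
        p = p.replace(I_GluT_max=0.0, I_NKA_max=0.0, I_NCX_max=0.0)
    if block_glut:
        p = p.replace(I_GluT_max=0.0)
    return p


def resting_ip3(p: ModelParameters, ca_i: float | None = None) -> float:
    """Resting IP3 (µM): bracketed root of d[IP3]/dt = 0 at zero glutamate."""
    ca = p.Ca_i_rest if ca_i is None else float(ca_i)
    f = lambda ip3: fluxes.ip3_rate(ca, ip3, 0.0, p)
    if f(0.0) <= 0 or f(1.0) >= 0:
        raise CalibrationError(
            "no sign change for d[IP3]/dt = 0 in (0, 1] µM")
    return float(brentq(f, 0.0, 1.0, xtol=1e-15))


@dataclass
class CalibrationResult:
    """Calibrated rest state plus the parameter record that realizes it.

    ``params`` carries the calibrated leak conductances and the calibrated
    rest anchors (Ca_i_rest, Ca_ER_rest) used by the extracellular
    constraints; ``state`` is the 7-component rest vector.
    """

    params: ModelParameters
    state: np.ndarray
    mode: str
    residual: float
    report: dict[str, Any] = field(default_factory=dict)

    @property
    def ip3_rest(self) -> float:
        return float(self.state[5])

    @property
    def h_rest(self) -> float:
        return float(self.state[6])

    @property
    def ca_er_rest(self) -> float:
        return float(self.state[1])

    @property
    def ca_i_rest(self) -> float:
        return float(self.state[0])


_PRINTED = dict(ip3_rest=0.15659, h_rest=0.7892, ca_er_rest=25.0,
                g_Na_leak=0.0065, g_K_leak=0.0791)


def calibrate_rest(p: ModelParameters | None = None,
                   geom: CompartmentGeometry | None = None,
                   mode: str = "self_consistent",
                   store_init: str = "balanced") -> CalibrationResult:
    """Compute the resting state and leak conductances.

    ``self_consistent`` (default) derives IP3_rest, h_rest, Ca_ER_rest,
    g_Na_leak and g_K_leak from the zero-derivative conditions (and, with an
    active NCX, resting Ca_i from the exchanger reversal), yielding an exact
    fixed point of :func:`rhs`.  ``printed`` uses the published table values
    verbatim; its residual is reported, not enforced.

    ``store_init`` selects the initial ER Ca2+ load, which in the
    store-release-only subsystem is a conserved quantity and therefore a
    genuine study condition rather than a numerical detail:

    * ``"balanced"``: the ER flux balance J_IP3R + J_leak = J_Serca with the
      Hill-form SERCA rate (≈ 8.8 µM); the rest is then an exact fixed point.
    * ``"printed"``: the published initial value (Ca_ER_rest, 25 µM), which
      equals the balance computed with SERCA running at its maximal rate.
      The published oscillation-onset and pathway-interaction results depend
      on this larger store load, so figure-reproduction experiments use it;
      the store then carries an initial re-equilibration transient and the
      rest is stationary in every variable except the Ca pools.
    """
    p = default_parameters() if p is None else p
    geom = CompartmentGeometry() if geom is None else geom
    if mode not in ("self_consistent", "printed"):
        raise ValueError("mode must be 'self_consistent' or 'printed'")
    if store_init not in ("balanced", "printed"):
        raise ValueError("store_init must be 'balanced' or 'printed'")

    if mode == "printed":
        p_cal = p
        state = np.array([p.Ca_i_rest, p.Ca_ER_rest, p.Na_i_rest, p.K_i_rest,
                          p.V_rest, _PRINTED["ip3_rest"], _PRINTED["h_rest"]])
    else:
        ncx_on = p.I_NCX_max > 0
        if ncx_on:
            ca_rest = fluxes.ncx_reversal_ca(p.Na_i_rest, p.Na_o_rest,
                                             p.Ca_o_rest, p.V_rest, p)
        else:
            ca_rest = p.Ca_i_rest
        ip3_rest = resting_ip3(p, ca_rest)
        h_rest = fluxes.h_inf(ca_rest, ip3_rest, p)
        if store_init == "printed" or not geom.has_er:
            ca_er_rest = p.Ca_ER_rest
        else:
            # J_IP3R + J_leak = J_Serca is linear in Ca_ER
            m = ip3_rest / (ip3_rest + p.d1)
            n = ca_rest / (ca_rest + p.d5)
            gate = p.r_C * (m * n * h_rest) ** 3
            ca_er_rest = ca_rest + fluxes.serca_flux(ca_rest, p) / (gate + p.r_L)
        e_na = fluxes.nernst(1, p.Na_o_rest, p.Na_i_rest, p)
        e_k = fluxes.nernst(1, p.K_o_rest, p.K_i_rest, p)
        i_nka = fluxes.nka_current(p.Na_i_rest, p.K_o_rest, p)
        i_ncx = fluxes.ncx_current(p.Na_i_rest, p.Na_o_rest, ca_rest,
                                   p.Ca_o_rest, p.V_rest, p)
        # d[Na]/dt = 0 and d[K]/dt = 0 at rest (I_GluT = 0 at zero glutamate)
        g_na = -3.0 * (i_nka + i_ncx) / (p.V_rest - e_na)
        g_k = 2.0 * i_nka / (p.V_rest - e_k)
        if g_na < 0 or g_k < 0:
            raise CalibrationError(
                f"leak calibration produced a negative conductance "
                f"(g_Na={g_na:.4g}, g_K={g_k:.4g} nS/µm²)")
        p_cal = p.replace(g_Na_leak=g_na, g_K_leak=g_k,
                          Ca_i_rest=float(ca_rest), Ca_ER_rest=float(ca_er_rest))
        state = np.array([ca_rest, ca_er_rest, p.Na_i_rest, p.K_i_rest,
                          p.V_rest, ip3_rest, h_rest])

    dy = rhs(state, 0.0, geom, p_cal)
    scale = np.maximum(np.abs(state), 1.0)
    residual = float(np.max(np.abs(dy) / scale))
    if mode == "self_consistent" and store_init == "balanced" \
            and residual > 1e-9:
        raise CalibrationError(
            f"calibrated rest is not stationary (scaled residual {residual:.3g})")

    report = {
        "mode": mode,
        "store_init": store_init,
        "ca_i_rest": float(state[0]),
        "ip3_rest": float(state[5]),
        "h_rest": float(state[6]),
        "ca_er_rest": float(state[1]),
        "g_Na_leak": float(p_cal.g_Na_leak),
        "g_K_leak": float(p_cal.g_K_leak),
        "printed": dict(_PRINTED, ca_i_rest=p.Ca_i_rest),
        "scaled_residual": residual,
    }
    log.info("calibration (%s): Ca_i=%.5g µM (printed %.5g), IP3=%.6g µM "
             "(printed %.5g), h=%.5g (printed %.5g), Ca_ER=%.5g µM (printed "
             "%.5g), g_Na_leak=%.5g (printed %.5g), g_K_leak=%.5g (printed "
             "%.5g), residual=%.3g",
             state[0], p.Ca_i_rest, state[5], _PRINTED["ip3_rest"], state[6],
             _PRINTED["h_rest"], state[1], _PRINTED["ca_er_rest"],
             p_cal.g_Na_leak, _PRINTED["g_Na_leak"], p_cal.g_K_leak,
             _PRINTED["g_K_leak"], residual)
    return CalibrationResult(params=p_cal, state=state, mode=mode,
                             residual=residual, report=report)


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Tidy time-indexed record of a run.

    ``data`` holds one row per saved step with the state variables, the
    synapse variables, the derived extracellular concentrations and the
    individual flux/current densities.  ``metadata`` reconstructs the run.
    """

    data: pd.DataFrame
    metadata: dict[str, Any]

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def __getitem__(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    @property
    def dt(self) -> float:
        return float(self.metadata["dt"])


def _flux_columns(df: pd.DataFrame, p: ModelParameters,
                  er_active: bool) -> None:
    """Recompute the full flux breakdown, vectorized, on the saved rows."""
    ca, caer = df["Ca_i"].to_numpy(), df["Ca_ER"].to_numpy()
    na, ki = df["Na_i"].to_numpy(), df["K_i"].to_numpy()
    v, ip3, h = df["V"].to_numpy(), df["IP3"].to_numpy(), df["h"].to_numpy()
    g = df["g"].to_numpy()
    cao, nao, ko = df["Ca_o"].to_numpy(), df["Na_o"].to_numpy(), df["K_o"].to_numpy()
    if er_active:
        df["J_IP3R"] = fluxes.ip3r_flux(ca, caer, ip3, h, p)
        df["J_Serca"] = fluxes.serca_flux(ca, p)
        df["J_CERleak"] = fluxes.er_leak_flux(ca, caer, p)
    else:
        df["J_IP3R"] = df["J_Serca"] = df["J_CERleak"] = 0.0
    df["I_GluT"] = fluxes.glut_current(ki, nao, g, p)
    df["I_NKA"] = fluxes.nka_current(na, ko, p)
    df["I_NCX"] = fluxes.ncx_current(na, nao, ca, cao, v, p)
    i_na, i_k = fluxes.leak_currents(v, na, nao, ki, ko, p)
    df["I_Na_leak"] = i_na
    df["I_K_leak"] = i_k
    pb, pd_, d3k, d5p = fluxes.ip3_production_degradation(ca, ip3, g, p)
    df["prod_PLCbeta"] = pb
    df["prod_PLCdelta"] = pd_
    df["degr_IP3_3K"] = d3k
    df["degr_IP_5P"] = d5p


def simulate(protocol: StimulusProtocol,
             params: ModelParameters | None = None,
             geometry: CompartmentGeometry | None = None,
             dt: float = 1e-3,
             save_every: int = 1,
             mglur_only: bool = False,
             block_glut: bool = False,
             er_free: bool = False,
             calibration: str = "self_consistent",
             store_init: str = "balanced",
             record_fluxes: bool = True) -> SimulationTrace:
    """Forward-Euler trajectory over the protocol duration (dt = 1 ms default).

    The run is calibrated to its own rest first (see :func:`calibrate_rest`),
    so an unstimulated simulation stays flat.  ``save_every`` thins the
    stored trace without affecting the integration grid.
    """
    p = default_parameters() if params is None else params
    geom = CompartmentGeometry() if geometry is None else geometry
    if er_free:
        geom = replace(geom, ratio_er=0.0)
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if save_every < 1:
        raise ValueError("save_every must be >= 1")

    p_eff = apply_toggles(p, mglur_only=mglur_only, block_glut=block_glut)
    cal = calibrate_rest(p_eff, geom, mode=calibration, store_init=store_init)
    p_cal = cal.params

    n_steps = int(round(protocol.duration / dt))
    if n_steps < 1:
        raise ValueError("protocol duration shorter than one time step")
    if n_steps % save_every != 0:
        raise ValueError("save_every must divide the number of steps "
                         f"({n_steps})")
    g_ext, x_syn, y_syn = glutamate_trace(protocol, dt, p_cal, n_steps)

    pv = _pack(p_cal, geom)
    out, status, k = _euler_loop(cal.state, g_ext, dt, save_every, pv)
    if status != 0:
        raise SimulationError(
            f"{_STATUS_MSG[status]} at step {k} (t = {k * dt:.4g} s)")

    sl = slice(None, None, save_every)
    df = pd.DataFrame(out, columns=list(STATE_NAMES))
    df.insert(0, "t", dt * save_every * np.arange(out.shape[0]))
    df["x"] = x_syn[sl]
    df["y"] = y_syn[sl]
    df["g"] = g_ext[sl]
    df["Ca_o"] = p_cal.Ca_o_rest + (df["Ca_i"] - p_cal.Ca_i_rest) \
        + (p_cal.Ca_ER_rest - df["Ca_ER"])
    df["Na_o"] = p_cal.Na_o_rest + (p_cal.Na_i_rest - df["Na_i"])
    df["K_o"] = p_cal.K_o_rest + (p_cal.K_i_rest - df["K_i"])
    if record_fluxes:
        _flux_columns(df, p_cal, er_active=geom.ratio_er > 0)

    metadata = {
        "dt": dt,
        "save_every": save_every,
        "duration": protocol.duration,
        "protocol": {"mode": protocol.mode, "rate": protocol.rate,
                     "duration": protocol.duration,
                     "glutamate_level": protocol.glutamate_level,
                     "spike_times": list(protocol.spike_times),
                     "seed": protocol.seed},
        "geometry": {"svr": geom.svr, "ratio_er": geom.ratio_er},
        "toggles": {"mglur_only": mglur_only, "block_glut": block_glut,
                    "er_free": er_free},
        "calibration": cal.report,
        "parameters": p_cal.to_dict(),
        "requested_parameters": p.to_dict(),
        "code_version": _code_version(),
    }
    return SimulationTrace(data=df, metadata=metadata)


def _code_version() -> str:
    from . import __version__
    return __version__


def integrate_reference(state0, g_of_t: Callable[[float], float],
                        geom: CompartmentGeometry, p: ModelParameters,
                        t_eval, rtol: float = 1e-8,
                        atol: float = 1e-10) -> np.ndarray:
    """Adaptive high-accuracy integration of the same RHS (LSODA).

    Cross-check oracle for the Euler scheme on smooth protocols (constant or
    no glutamate); returns states at ``t_eval`` with shape (len(t_eval), 7).
    """
    from scipy.integrate import solve_ivp

    pv = _pack(p, geom)

    def f(t, y):
        dy = np.empty(7)
        status = _rhs_into(y, float(g_of_t(t)), pv, dy)
        if status != 0:
            raise SimulationError(_STATUS_MSG[status])
        return dy

    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(f, (float(t_eval[0]), float(t_eval[-1])),
                    np.asarray(state0, dtype=float), method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise SimulationError(f"reference integrator failed: {sol.message}")
    return sol.y.T
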