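"""Pure flux/current functions.

Every transport process is a pure function of the instantaneous state and
the parameter record.  ER fluxes (IP3R channel, SERCA pump, ER leak) are
returned as volumetric rates in µM/s — their F*Vol/A current prefactor is
cancelled analytically against the A/(F*Vol) of the concentration balance.
Plasma-membrane transporters (GluT, NKA, NCX, leaks) are current densities
in pA/µm².  All functions broadcast over numpy arrays.

Sign conventions follow the balance equations of the source model, not
physiology texts:

* positive ER flux moves Ca2+ from the ER lumen into the cytosol;
* positive I_NCX raises cytosolic Ca2+ (reverse mode: 3 Na+ out / 1 Ca2+ in);
* I_GluT, I_NKA and the ohmic leaks are non-negative magnitudes whose signs
  are applied by the balance equations themselves.
"""

from __future__ import annotations

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "ip3r_flux", "h_inf", "h_rate", "serca_flux", "er_leak_flux",
    "ip3_production_degradation", "ip3_rate", "glut_current", "nka_current",
    "ncx_current", "nernst", "leak_currents",
]


# --------------------------------------------------------------------------
# ER membrane (volumetric rates, µM/s)
# --------------------------------------------------------------------------

def ip3r_flux(ca_i, ca_er, ip3, h, p: ModelParameters):
    """IP3-receptor channel flux r_C * m∞³ n∞³ h³ * ([Ca]_ER - [Ca]_i), µM/s.

    m∞ and n∞ are the IP3- and Ca-activation occupancies of the three
    channel subunits; h is the fraction not inactivated by Ca2+.
    """
    m = ip3 / (ip3 + p.d1)
    n = ca_i / (ca_i + p.d5)
    return p.r_C * (m * n * h) ** 3 * (ca_er - ca_i)


def h_inf(ca_i, ip3, p: ModelParameters):
    """Steady-state fraction of non-inactivated IP3R channels."""
    q2 = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    return q2 / (q2 + ca_i)


def h_rate(ca_i, ip3, h, p: ModelParameters):
    """dh/dt = a2 * (Q2 * (1 - h) - h * [Ca]_i), 1/s."""
    q2 = p.d2 * (ip3 + p.d1) / (ip3 + p.d3)
    return p.a2 * (q2 * (1.0 - h) - h * ca_i)


def serca_flux(ca_i, p: ModelParameters):
    """SERCA uptake v_ER * [Ca]_i² / ([Ca]_i² + K_ER²), µM/s (into the ER)."""
    ca2 = ca_i * ca_i
    return p.v_ER * ca2 / (ca2 + p.K_ER * p.K_ER)


def er_leak_flux(ca_i, ca_er, p: ModelParameters):
    """Passive ER leak r_L * ([Ca]_ER - [Ca]_i), µM/s."""
    return p.r_L * (ca_er - ca_i)


# --------------------------------------------------------------------------
# IP3 metabolism (µM/s)
# --------------------------------------------------------------------------

def ip3_production_degradation(ca_i, ip3, g, p: ModelParameters):
    """The four named IP3 source/sink terms, each ≥ 0, in µM/s.

    Returns (prod_PLCbeta, prod_PLCdelta, degr_IP3_3K, degr_IP_5P).
    prod_PLCbeta is the glutamate (mGluR) drive with a Hill exponent of 0.7
    and a Ca-dependent midpoint; g = 0 yields an exact zero (no 0**0.7
    ambiguity).
    """
    g = np.asarray(g, dtype=float)
    ca_i = np.asarray(ca_i, dtype=float)
    mid = (p.K_R + p.K_p * ca_i / (ca_i + p.K_pi)) ** 0.7
    g07 = np.where(g > 0, np.power(np.where(g > 0, g, 1.0), 0.7), 0.0)
    prod_beta = p.v_beta * g07 / (g07 + mid)
    ca2 = ca_i * ca_i
    prod_delta = (p.v_delta / (1.0 + ip3 / p.kappa_delta)
                  * ca2 / (ca2 + p.K_PLCdelta * p.K_PLCdelta))
    ca4 = ca2 * ca2
    degr_3k = (p.v_3K * ca4 / (ca4 + p.K_D ** 4) * ip3 / (ip3 + p.K_3))
    degr_5p = p.r_5P * ip3
    if prod_beta.ndim == 0:
        return float(prod_beta), float(prod_delta), float(degr_3k), float(degr_5p)
    return prod_beta, prod_delta, degr_3k, degr_5p


def ip3_rate(ca_i, ip3, g, p: ModelParameters):
    """Net d[IP3]/dt in µM/s (production minus degradation)."""
    pb, pd, d3k, d5p = ip3_production_degradation(ca_i, ip3, g, p)
    return pb + pd - d3k - d5p


# --------------------------------------------------------------------------
# Plasma membrane (current densities, pA/µm²)
# --------------------------------------------------------------------------

def glut_current(k_i, na_o, g, p: ModelParameters):
    """Glutamate-transporter current, bounded in [0, I_GluT_max].

    Product of K+ (intracellular), Na+ (extracellular, cubic) and glutamate
    saturation factors.  Each transport cycle carries 3 Na+ and 1 H+ in and
    1 K+ out (net +2 charge); the stoichiometry is applied in the balance
    equations.
    """
    na3 = na_o ** 3
    return (p.I_GluT_max
            * k_i / (k_i + p.K_GluT_mK)
            * na3 / (na3 + p.K_GluT_mN ** 3)
            * g / (g + p.K_GluT_mg))


def nka_current(na_i, k_o, p: ModelParameters):
    """Na+/K+-ATPase current, bounded in [0, I_NKA_max] (3 Na+ out, 2 K+ in)."""
    na15 = na_i ** 1.5
    return (p.I_NKA_max
            * na15 / (na15 + p.K_NKA_mN ** 1.5)
            * k_o / (k_o + p.K_NKA_mK))


def ncx_current(na_i, na_o, ca_i, ca_o, v, p: ModelParameters):
    """Na+/Ca2+ exchanger current (3 Na+ : 1 Ca2+), pA/µm².

    Positive in reverse mode (Ca2+ entry, Na+ exit), negative in forward
    mode; exactly zero at the thermodynamic reversal voltage
    V_rev = (RT/F) * ln([Ca]_i [Na]_o³ / ([Ca]_o [Na]_i³)).
    Units: Na in mM, Ca in µM, v in mV.
    """
    phi = v / p.rtf
    e_fwd = np.exp(p.eta * phi)
    e_rev = np.exp((p.eta - 1.0) * phi)
    na_o3 = na_o ** 3
    pre = (p.I_NCX_max
           * na_o3 / (p.K_NCX_mN ** 3 + na_o3)
           * ca_o / (p.K_NCX_mC + ca_o))
    num = (na_i / na_o) ** 3 * e_fwd - (ca_i / ca_o) * e_rev
    return pre * num / (1.0 + p.k_sat * e_rev)


def ncx_reversal_ca(na_i, na_o, ca_o, v, p: ModelParameters):
    """Cytosolic Ca2+ (µM) at which the NCX current vanishes (closed form)."""
    return ca_o * (na_i / na_o) ** 3 * np.exp(v / p.rtf)


def nernst(z, c_o, c_i, p: ModelParameters):
    """Nernst reversal potential (mV) for valence ``z``; concentrations > 0."""
    c_o = np.asarray(c_o, dtype=float)
    c_i = np.asarray(c_i, dtype=float)
    if np.any(c_o <= 0) or np.any(c_i <= 0):
        raise ValueError("Nernst potential needs strictly positive concentrations")
    out = p.rtf / z * np.log(c_o / c_i)
    return float(out) if out.ndim == 0 else out


def leak_currents(v, na_i, na_o, k_i, k_o, p: ModelParameters):
    """Ohmic Na+ and K+ leaks g * (V - E) with Nernst reversals, pA/µm²."""
    e_na = nernst(1, na_o, na_i, p)
    e_k = nernst(1, k_o, k_i, p)
    return p.g_Na_leak * (v - e_na), p.g_K_leak * (v - e_k)
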