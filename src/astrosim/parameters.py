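"""Model constants for the two-pathway astrocyte compartment model.

All biophysical constants live in a single immutable :class:`ModelParameters`
record.  Defaults are the published table values of the source model.  The
internal unit system is:

* Ca2+, IP3 and extracellular glutamate concentrations in µM
* Na+ and K+ concentrations in mM
* membrane voltage in mV, time in s
* current densities in pA/µm², conductances in nS/µm²
* membrane capacitance in pF/µm²

Two constants are not published and are exposed here with documented
defaults: the temperature ``T`` (310 K, so RT/F ≈ 26.7 mV) and the specific
membrane capacitance ``C_m``.  The calibrated leak conductances slave the
membrane voltage to the ionic state with a time constant C_m/Σg that is far
below every other timescale of the model, so ``C_m`` acts purely as a
numerical relaxation constant; the default 1.0 pF/µm² keeps that relaxation
(≈ 6 ms) comfortably resolved by the 1 ms forward-Euler grid while leaving
the slow dynamics unchanged (verified against an adaptive stiff integrator,
see docs/methods.md).
The total vesicular glutamate content ``G_T`` of the synapse model is also
not published; the default 200 mM makes ``rho_C * G_T`` = 130 µM, i.e. the
per-release cleft transient is in the tens of µM, commensurate with the
transporter glutamate affinity K_GluT_mg = 34 µM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, fields
from typing import Any, Mapping


@dataclass(frozen=True)
class ModelParameters:
    # --- IP3 production and degradation (PLCbeta, PLCdelta, IP3-3K, IP-5P) ---
    v_beta: float = 0.05          # µM/s  maximal PLCbeta production rate
    K_R: float = 1.3              # µM    glutamate affinity of the receptor
    K_p: float = 10.0             # µM    Ca/PLC-dependent inhibition factor
    K_pi: float = 0.6             # µM    Ca affinity of PLC
    v_delta: float = 0.02         # µM/s  maximal PLCdelta production rate
    kappa_delta: float = 1.5      # µM    IP3 inhibition constant of PLCdelta
    K_PLCdelta: float = 0.1       # µM    Ca affinity of PLCdelta
    v_3K: float = 2.0             # µM/s  maximal IP3-3K degradation rate
    K_D: float = 0.7              # µM    Ca affinity of IP3-3K
    K_3: float = 1.0              # µM    IP3 affinity of IP3-3K
    r_5P: float = 0.04            # 1/s   IP-5P degradation rate

    # --- ER membrane fluxes: IP3R channel, SERCA pump, leak ---
    r_C: float = 6.0              # 1/s   maximal IP3R channel rate
    d1: float = 0.13              # µM    IP3 dissociation constant
    d5: float = 0.08234           # µM    Ca activation dissociation constant
    v_ER: float = 4.0             # µM/s  maximal SERCA uptake rate
    K_ER: float = 0.1             # µM    SERCA Ca affinity
    r_L: float = 0.11             # 1/s   ER leak rate
    a2: float = 0.2               # 1/(µM s)  IP3R Ca-inhibition binding rate
    d2: float = 1.049             # µM    Ca inactivation dissociation constant
    d3: float = 0.9434            # µM    IP3 inactivation dissociation constant

    # --- plasma-membrane transporters ---
    I_GluT_max: float = 0.68      # pA/µm²  maximal glutamate-transporter current
    K_GluT_mN: float = 15.0       # mM      GluT Na+ half saturation
    K_GluT_mK: float = 5.0        # mM      GluT K+ half saturation
    K_GluT_mg: float = 34.0       # µM      GluT glutamate half saturation
    I_NKA_max: float = 1.52       # pA/µm²  maximal Na+/K+-ATPase current
    K_NKA_mN: float = 10.0        # mM      NKA Na+ half saturation
    K_NKA_mK: float = 1.5         # mM      NKA K+ half saturation
    I_NCX_max: float = 0.1        # pA/µm²  maximal Na+/Ca2+ exchanger current
    K_NCX_mN: float = 87.5        # mM      NCX Na+ half saturation (87500 µM)
    K_NCX_mC: float = 1380.0      # µM      NCX Ca2+ half saturation
    k_sat: float = 0.1            # -       NCX saturation factor
    eta: float = 0.35             # -       NCX energy-barrier position
    g_Na_leak: float = 0.0065     # nS/µm²  Na+ leak conductance (recalibrated by default)
    g_K_leak: float = 0.0791      # nS/µm²  K+ leak conductance (recalibrated by default)

    # --- Tsodyks-Markram synapse ---
    # The source tables print the three time constants with inverse-second
    # units ("2 s^-1", "1 s^-1", "60 s^-1").  `tm_taus_are_rates` selects how
    # the numbers are read: True (default) treats them as rates, i.e. the
    # effective time constants are 1/2 s, 1 s and 1/60 s; False uses the
    # printed numbers directly as the ODE denominators (2 s, 1 s, 60 s).
    # The rate reading gives millisecond-scale cleft clearance and is the one
    # that reproduces the published oscillation-onset and pathway-block
    # results (see docs/methods.md).
    tau_facil: float = 2.0        # s or 1/s, see tm_taus_are_rates
    tau_rec: float = 1.0          # s or 1/s
    tau_clear: float = 60.0       # s or 1/s
    tm_taus_are_rates: bool = True
    U_0: float = 0.25             # -     utilization increment per spike
    rho_C: float = 6.5e-4         # -     vesicle/cleft volume ratio
    G_T: float = 200000.0         # µM    total vesicular glutamate (200 mM, see module docstring)

    # --- physical constants ---
    F: float = 96485.0            # C/mol Faraday constant
    R: float = 8.314              # J/(mol K) gas constant
    T: float = 310.0              # K     temperature
    C_m: float = 1.0              # pF/µm² membrane capacitance (see module docstring)

    # --- resting (initial) concentrations and voltage ---
    Ca_i_rest: float = 0.073      # µM
    Ca_ER_rest: float = 25.0      # µM  (printed value; self-consistent calibration recomputes it)
    Ca_o_rest: float = 1800.0     # µM
    Na_i_rest: float = 15.0       # mM
    Na_o_rest: float = 145.0      # mM
    K_i_rest: float = 100.0       # mM
    K_o_rest: float = 3.0         # mM
    V_rest: float = -85.0         # mV

    def __post_init__(self) -> None:
        positive = (
            "v_beta", "K_R", "K_p", "K_pi", "v_delta", "kappa_delta",
            "K_PLCdelta", "v_3K", "K_D", "K_3", "r_5P", "r_C", "d1", "d5",
            "v_ER", "K_ER", "r_L", "a2", "d2", "d3", "K_GluT_mN", "K_GluT_mK",
            "K_GluT_mg", "K_NKA_mN", "K_NKA_mK", "K_NCX_mN", "K_NCX_mC",
            "tau_facil", "tau_rec", "tau_clear", "rho_C", "G_T", "F", "R",
            "T", "C_m", "Ca_i_rest", "Ca_ER_rest", "Ca_o_rest", "Na_i_rest",
            "Na_o_rest", "K_i_rest", "K_o_rest",
        )
        nonnegative = ("I_GluT_max", "I_NKA_max", "I_NCX_max",
                       "g_Na_leak", "g_K_leak")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name!r} must be > 0, "
                                 f"got {getattr(self, name)!r}")
        for name in nonnegative:
            if not getattr(self, name) >= 0:
                raise ValueError(f"parameter {name!r} must be >= 0, "
                                 f"got {getattr(self, name)!r}")
        if not 0 < self.k_sat <= 1:
            raise ValueError(f"k_sat must be in (0, 1], got {self.k_sat!r}")
        if not 0 < self.eta < 1:
            raise ValueError(f"eta must be in (0, 1), got {self.eta!r}")
        if not 0 < self.U_0 <= 1:
            raise ValueError(f"U_0 must be in (0, 1], got {self.U_0!r}")

    # -- convenience -----------------------------------------------------
    @property
    def rtf(self) -> float:
        """RT/F in mV."""
        return 1e3 * self.R * self.T / self.F

    def tm_time_constants(self) -> tuple[float, float, float]:
        """Effective (tau_facil, tau_rec, tau_clear) in seconds."""
        if self.tm_taus_are_rates:
            return 1.0 / self.tau_facil, 1.0 / self.tau_rec, 1.0 / self.tau_clear
        return self.tau_facil, self.tau_rec, self.tau_clear

    def replace(self, **overrides: Any) -> "ModelParameters":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


_FIELD_NAMES = frozenset(f.name for f in fields(ModelParameters))


def default_parameters() -> ModelParameters:
    """Return the full published default parameter set."""
    return ModelParameters()


def load_parameters(config: Mapping[str, Any] | None) -> ModelParameters:
    """Build a parameter set from a flat mapping of overrides.

    Unspecified fields take their defaults; unknown keys are rejected by
    name; validation runs on the merged result.
    """
    if not config:
        return ModelParameters()
    unknown = sorted(set(config) - _FIELD_NAMES)
    if unknown:
        raise KeyError(f"unknown parameter key(s): {', '.join(unknown)}")
    return ModelParameters(**dict(config))
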