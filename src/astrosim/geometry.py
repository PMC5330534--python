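"""Compartment geometry: SVR, ER volume ratio and current-to-rate scaling.

The compartment is a short cylinder; because both the curved surface area A
and the volume Vol scale linearly with the cylinder length, the ratio
SVR = A/Vol is independent of length and is the only geometric quantity the
concentration balance needs.  The ER is a concentric inner cylinder whose
volume (and membrane area) is the intracellular one scaled by ``ratio_er``.

Empirically, along an astrocytic process the two quantities co-vary:

    ratio_er(SVR) = 0.15 * exp(-(0.002 * SVR) ** 2.32)

This map is a convenience, not a hard constraint: simulations may pin SVR
(membrane-flux scale) and sweep ``ratio_er`` (store size) independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

RATIO_ER_MAX = 0.15
_SVR_SCALE = 0.002   # µm: multiplies SVR in the empirical map
_SVR_EXPONENT = 2.32


def ratio_er_from_svr(svr):
    """ER-to-intracellular volume ratio for a given surface-to-volume ratio.

    Strictly decreasing in ``svr`` (1/µm), bounded in (0, 0.15].
    """
    svr = np.asarray(svr, dtype=float)
    if np.any(svr < 0):
        raise ValueError("SVR must be non-negative")
    out = RATIO_ER_MAX * np.exp(-((_SVR_SCALE * svr) ** _SVR_EXPONENT))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CompartmentGeometry:
    """Outer-membrane surface-to-volume ratio (1/µm) and ER volume fraction.

    If ``ratio_er`` is None it is derived from ``svr`` through the empirical
    map above.
    """

    svr: float = 1.0
    ratio_er: float | None = None

    def __post_init__(self) -> None:
        if not self.svr > 0:
            raise ValueError(f"svr must be > 0, got {self.svr!r}")
        if self.ratio_er is None:
            object.__setattr__(self, "ratio_er", ratio_er_from_svr(self.svr))
        if not 0 <= self.ratio_er <= RATIO_ER_MAX:
            raise ValueError(
                f"ratio_er must be in [0, {RATIO_ER_MAX}], got {self.ratio_er!r}")

    @property
    def has_er(self) -> bool:
        return self.ratio_er > 0


def membrane_rate_factor(geom: CompartmentGeometry | float, p) -> float:
    """µM/s of concentration change per pA/µm² of membrane current density.

    Derivation (the one unit-conversion in the package): a current density I
    (pA/µm²) through a membrane with surface-to-volume ratio SVR (1/µm)
    moves charge at I*SVR pA/µm³ = I*SVR * 1e-12 C/s per 1e-15 L
    = I*SVR * 1e3 C/(s L).  Dividing by Faraday's constant gives mol/(L s)
    and multiplying by 1e6 gives µM/s, i.e. a net factor SVR * 1e9 / F.
    The printed balance equations fold ion stoichiometry into the summed
    currents, so no valence appears here.  For species tracked in mM divide
    by a further 1e3.
    """
    svr = geom.svr if isinstance(geom, CompartmentGeometry) else float(geom)
    if svr < 0:
        raise ValueError("SVR must be non-negative")
    return svr * 1e9 / p.F


def er_rate_factors(geom: CompartmentGeometry) -> tuple[float, float]:
    """(cytosolic, ER-lumen) multipliers for the volumetric ER fluxes.

    The ER fluxes are expressed directly as volumetric rates J (µM/s): the
    F*Vol/A prefactor in their current definitions cancels against the
    A/(F*Vol) of the concentration balance.  The cytosol sees ratio_er * J
    (ER membrane area is scaled by ratio_er); the ER lumen sees -J with a
    unit factor (the ratio_er in area and volume cancels), so total Ca2+ is
    conserved between the two pools: Vol*d[Ca]_i|_ER + Vol*ratio_er*d[Ca]_ER = 0.
    """
    return geom.ratio_er, 1.0
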