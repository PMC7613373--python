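"""Leaf optical properties: generalized plate model with protein / carbon split.

The leaf is represented as ``N_struct`` compact absorbing plates separated by
air spaces.  Absorption of one elementary layer is the sum of the constituent
contents times their specific absorption coefficients, divided by
``N_struct``; dry matter is split into protein content and carbon-based
constituents so that nitrogen can be traced through the protein pathway.
Reflectance and transmittance of the stack follow from the single-plate
solution extended to ``N_struct`` layers by the Stokes system.

Optical constants come from :mod:`cncmap.rtm.optical_constants` (synthetic
parametric tables; see that module's docstring).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy.special import exp1

from .optical_constants import MODEL_WAVELENGTHS_NM, optical_constants

__all__ = ["LeafParams", "LeafOptics", "prospect_pro", "tav"]

#: Incidence half-angle (degrees) of the top leaf surface for near-collimated
#: illumination; the standard value for slightly rough cuticles.
SURFACE_INCIDENCE_DEG = 40.0


@dataclass(frozen=True)
class LeafParams:
    """Leaf structure and biochemistry driving the plate model.

    N_struct : leaf structure parameter (number of plates, >= 1)
    C_ab     : chlorophyll a+b content, ug/cm^2
    C_xc     : carotenoid content, ug/cm^2
    C_anth   : anthocyanin content, ug/cm^2
    C_w      : equivalent water thickness, cm
    C_p      : protein content, g/cm^2
    CBC      : carbon-based constituents, g/cm^2
    """

    N_struct: float
    C_ab: float
    C_xc: float
    C_anth: float
    C_w: float
    C_p: float
    CBC: float

    def __post_init__(self) -> None:
        if self.N_struct < 1.0:
            raise ValueError("N_struct must be >= 1")
        for name in ("C_ab", "C_xc", "C_anth", "C_w", "C_p", "CBC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class LeafOptics(NamedTuple):
    wavelengths: np.ndarray
    reflectance: np.ndarray
    transmittance: np.ndarray


def tav(alpha_deg: float, n: np.ndarray) -> np.ndarray:
    """Transmissivity of a dielectric interface averaged over incidence angles.

    Average Fresnel transmissivity (unpolarized) of a plane surface of
    refractive index ``n`` illuminated isotropically within a cone of
    half-angle ``alpha_deg`` (90 gives the full hemisphere)::

        tav(a) = 2/sin^2(a) * int_0^a T(theta) sin(theta) cos(theta) dtheta

    evaluated by Gauss-Legendre quadrature (64 nodes, accurate to ~1e-10).
    """
    n = np.asarray(n, dtype=float)
    if alpha_deg == 0:
        return 4.0 * n / (n + 1.0) ** 2
    alpha = np.radians(alpha_deg)
    nodes, wts = np.polynomial.legendre.leggauss(64)
    theta = 0.5 * alpha * (nodes + 1.0)  # map [-1, 1] -> [0, alpha]
    ci = np.cos(theta)[:, None]
    si = np.sin(theta)[:, None]
    st = si / n[None, :]  # Snell; n > 1 so no total internal reflection
    ct = np.sqrt(1.0 - st**2)
    rs = ((ci - n * ct) / (ci + n * ct)) ** 2
    rp = ((n * ci - ct) / (n * ci + ct)) ** 2
    transm = 1.0 - 0.5 * (rs + rp)
    integral = 0.5 * alpha * ((transm * si * ci).T @ wts)
    return 2.0 * integral / np.sin(alpha) ** 2


@lru_cache(maxsize=4)
def _cached_tav(alpha_deg: float) -> np.ndarray:
    """tav evaluated on the cached refractive-index spectrum."""
    return tav(alpha_deg, optical_constants().refractive_index)


def _plate_transmissivity(k: np.ndarray) -> np.ndarray:
    """Isotropic transmissivity of one absorbing plate of optical depth k."""
    theta = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    theta[pos] = (1.0 - kp) * np.exp(-kp) + kp**2 * exp1(kp)
    return theta


def prospect_pro(leaf: LeafParams) -> LeafOptics:
    """Directional-hemispherical reflectance and transmittance of a leaf.

    Returns spectra on the native 1 nm grid, 400-2500 nm.  Energy is
    conserved: ``r + t <= 1`` at every wavelength, with equality in the
    absorption-free limit.
    """
    oc = optical_constants()
    n = oc.refractive_index
    k = (
        leaf.C_ab * oc.k_chlorophyll
        + leaf.C_xc * oc.k_carotenoid
        + leaf.C_anth * oc.k_anthocyanin
        + leaf.C_w * oc.k_water
        + leaf.C_p * oc.k_protein
        + leaf.CBC * oc.k_cbc
    ) / leaf.N_struct
    theta = _plate_transmissivity(k)

    # Single plate with a restricted-cone top surface and hemispheric internal
    # interfaces.
    talf = _cached_tav(SURFACE_INCIDENCE_DEG)
    ralf = 1.0 - talf
    t12 = _cached_tav(90.0)
    r12 = 1.0 - t12
    t21 = t12 / n**2
    r21 = 1.0 - t21
    denom = 1.0 - r21**2 * theta**2
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    # Stokes extension to N_struct - 1 additional layers.  Guard the two
    # degenerate limits: opaque plates (t -> 0) transmit nothing through the
    # stack, and conservative scattering (r + t -> 1) needs its own formula.
    nn = leaf.N_struct - 1.0
    opaque = t < 1e-9
    cons = ~opaque & ((r + t) >= 1.0 - 1e-12)
    regular = ~opaque & ~cons
    Rsub = np.where(opaque, r, 0.0)
    Tsub = np.zeros_like(t)
    if np.any(regular):
        rr, tt = r[regular], t[regular]
        D = np.sqrt(
            np.clip((1.0 + rr + tt) * (1.0 + rr - tt) * (1.0 - rr + tt) * (1.0 - rr - tt), 0.0, None)
        )
        rq = rr * rr
        tq = tt * tt
        a = (1.0 + rq - tq + D) / (2.0 * rr)
        b = (1.0 - rq + tq + D) / (2.0 * tt)
        bNm1 = b**nn
        bN2 = bNm1 * bNm1
        a2 = a * a
        denom2 = a2 * bN2 - 1.0
        Rsub[regular] = a * (bN2 - 1.0) / denom2
        Tsub[regular] = bNm1 * (a2 - 1.0) / denom2
    if np.any(cons):
        tc = t[cons]
        Tsub[cons] = tc / (tc + (1.0 - tc) * nn)
        Rsub[cons] = 1.0 - Tsub[cons]

    denom3 = 1.0 - Rsub * r
    T = Ta * Tsub / denom3
    R = Ra + Ta * Rsub * t / denom3
    return LeafOptics(MODEL_WAVELENGTHS_NM, np.clip(R, 0.0, 1.0), np.clip(T, 0.0, 1.0))
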