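"""Synthetic leaf optical constants and reference soil spectrum.

SYNTHETIC DATA: the refractive index, the specific absorption coefficient
spectra (chlorophyll, carotenoids, anthocyanins, water, protein,
carbon-based constituents) and the reference dry-soil spectrum defined here
are parametric stand-ins built from Gaussian absorption features placed at
the physically documented wavelengths with amplitudes of realistic
magnitude.  They are NOT the published laboratory calibration tables of the
leaf optics literature; simulations made with them are qualitatively
realistic (pigment absorption in the visible, a NIR plateau, water bands at
1450/1940 nm, subtle protein features in the SWIR) but not quantitatively
identical to any calibrated model version.

All spectra are defined on the 1 nm model grid, 400-2500 nm.

Units: absorption coefficients are per unit of the corresponding leaf
constituent — cm^2/ug for pigments, 1/cm for water, cm^2/g for protein and
carbon-based constituents — so that ``content * coefficient`` is the
dimensionless optical depth contribution of one elementary layer.
"""

from __future__ import annotations

from functools import lru_cache
from typing import NamedTuple

import numpy as np

__all__ = ["OpticalConstants", "optical_constants", "soil_reflectance", "MODEL_WAVELENGTHS_NM"]

#: Native model grid (1 nm).
MODEL_WAVELENGTHS_NM = np.arange(400.0, 2501.0, 1.0)


def _g(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-amplitude Gaussian feature."""
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


class OpticalConstants(NamedTuple):
    wavelengths: np.ndarray  # nm
    refractive_index: np.ndarray
    k_chlorophyll: np.ndarray  # cm^2/ug
    k_carotenoid: np.ndarray  # cm^2/ug
    k_anthocyanin: np.ndarray  # cm^2/ug
    k_water: np.ndarray  # 1/cm
    k_protein: np.ndarray  # cm^2/g
    k_cbc: np.ndarray  # cm^2/g


@lru_cache(maxsize=1)
def optical_constants() -> OpticalConstants:
    """Synthetic leaf optical constants on the 1 nm model grid (cached)."""
    wl = MODEL_WAVELENGTHS_NM

    # Leaf interior refractive index: ~1.52 in the blue, slowly relaxing to
    # ~1.42 in the SWIR, essentially flat beyond ~1500 nm.
    n = 1.42 + 0.10 * np.exp(-(wl - 400.0) / 700.0)

    # Chlorophyll a+b: Soret band near 430 nm, red band near 662 nm, green gap.
    k_cab = (
        0.070 * _g(wl, 430.0, 35.0)
        + 0.035 * _g(wl, 470.0, 40.0)
        + 0.062 * _g(wl, 662.0, 28.0)
        + 0.015 * _g(wl, 600.0, 50.0)
    )
    # Carotenoids: blue absorbers only.
    k_car = 0.056 * _g(wl, 450.0, 32.0) + 0.042 * _g(wl, 485.0, 28.0)
    # Anthocyanins: green absorption near 550 nm.
    k_anth = 0.065 * _g(wl, 547.0, 35.0)
    # Liquid water: overtone bands at 970/1200 nm, strong bands at 1450 and
    # 1940 nm, rising continuum towards 2500 nm.
    k_w = (
        0.45 * _g(wl, 970.0, 45.0)
        + 1.20 * _g(wl, 1200.0, 55.0)
        + 29.0 * _g(wl, 1450.0, 55.0)
        + 3.0 * _g(wl, 1780.0, 70.0)
        + 110.0 * _g(wl, 1940.0, 70.0)
        + 45.0 * _g(wl, 2500.0, 220.0)
        + 6.0 * _g(wl, 2250.0, 120.0)
    )
    # Protein: N-H/C-H combination and overtone features — subtle NIR features
    # near 910/1020 nm and the stronger SWIR complex (1510, 1730, 1980, 2054,
    # 2172, 2300 nm).
    k_prot = (
        30.0 * _g(wl, 910.0, 25.0)
        + 35.0 * _g(wl, 1020.0, 25.0)
        + 70.0 * _g(wl, 1510.0, 30.0)
        + 80.0 * _g(wl, 1730.0, 30.0)
        + 90.0 * _g(wl, 1980.0, 35.0)
        + 160.0 * _g(wl, 2054.0, 30.0)
        + 150.0 * _g(wl, 2172.0, 35.0)
        + 60.0 * _g(wl, 2300.0, 40.0)
    )
    # Carbon-based constituents (cellulose/lignin/starch): broad dry-matter
    # absorption across the SWIR.
    k_cbc = (
        15.0 * _g(wl, 1450.0, 90.0)
        + 55.0 * _g(wl, 1720.0, 80.0)
        + 75.0 * _g(wl, 2100.0, 140.0)
        + 95.0 * _g(wl, 2340.0, 110.0)
    )
    return OpticalConstants(wl, n, k_cab, k_car, k_anth, k_w, k_prot, k_cbc)


@lru_cache(maxsize=1)
def soil_reflectance() -> np.ndarray:
    """Synthetic reference dry-soil reflectance on the 1 nm model grid.

    A smooth brightness ramp typical of dry bare soil with shallow moisture
    dips at the water bands and a mild clay feature near 2200 nm.  The canopy
    model scales this spectrum linearly with the soil scaling factor.
    """
    wl = MODEL_WAVELENGTHS_NM
    rho = (
        0.08
        + 0.32 * (1.0 - np.exp(-(wl - 400.0) / 1100.0))
        - 0.050 * _g(wl, 1450.0, 90.0)
        - 0.080 * _g(wl, 1940.0, 110.0)
        - 0.040 * _g(wl, 2210.0, 120.0)
    )
    return np.clip(rho, 0.02, 0.9)
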