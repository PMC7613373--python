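"""Pixel-level spectral cleaning for spaceborne imaging spectroscopy.

The cleaning chain removes the artifacts typical of pushbroom hyperspectral
reflectance products before a pixel reaches the retrieval model:

1. ``despike`` masks isolated single-band spikes and dips whose prominence
   exceeds a reflectance threshold (default 0.018);
2. ``exclude_windows`` masks bands inside known noisy wavelength intervals;
3. ``spline_gapfill`` fits a smoothing cubic spline through the surviving
   bands and evaluates it at every band center, closing the gaps;
4. the result is subset to the harmonized band set shared by field, satellite
   and simulated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .bands import BandGrid, MaskedSpectrum, Spectrum, harmonized_mask

__all__ = [
    "DESPIKE_THRESHOLD",
    "NOISY_WINDOWS_NM",
    "ExclusionWindows",
    "despike",
    "exclude_windows",
    "spline_gapfill",
    "PreprocessConfig",
    "preprocess_pixel",
]

#: Default prominence threshold (reflectance units) for spike/dip masking.
DESPIKE_THRESHOLD = 0.018

#: Noisy spectral regions systematically excluded before gap filling
#: (atmospheric residuals and detector artifacts identified against ground
#: reference spectra).
NOISY_WINDOWS_NM = (
    (535.0, 550.0),
    (755.0, 780.0),
    (810.0, 855.0),
    (885.0, 970.0),
    (1015.0, 1050.0),
    (1080.0, 1165.0),
    (1225.0, 1285.0),
    (1330.0, 1490.0),
    (1685.0, 1700.0),
    (1725.0, 1750.0),
    (1780.0, 1960.0),
    (1990.0, 2030.0),
)


@dataclass(frozen=True)
class ExclusionWindows:
    """Normalized list of closed [lo, hi] nm intervals."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        norm: list[list[float]] = []
        for lo, hi in sorted((float(lo), float(hi)) for lo, hi in self.intervals):
            if lo >= hi:
                raise ValueError(f"window [{lo}, {hi}] must have lo < hi")
            if norm and lo <= norm[-1][1]:
                norm[-1][1] = max(norm[-1][1], hi)  # merge overlaps
            else:
                norm.append([lo, hi])
        object.__setattr__(self, "intervals", tuple((a, b) for a, b in norm))

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        wavelengths = np.asarray(wavelengths, dtype=float)
        hit = np.zeros(wavelengths.shape, dtype=bool)
        for lo, hi in self.intervals:
            hit |= (wavelengths >= lo) & (wavelengths <= hi)
        return hit


def _as_masked(s: Spectrum | MaskedSpectrum) -> MaskedSpectrum:
    if isinstance(s, MaskedSpectrum):
        return s
    return MaskedSpectrum(s.grid, s.values)


def despike(s: Spectrum | MaskedSpectrum, threshold: float = DESPIKE_THRESHOLD) -> MaskedSpectrum:
    """Mask single-band spikes and dips rising above both immediate neighbors.

    A band is an artifact when it is a local extremum and its prominence over
    the nearer neighbor — ``min(|v[i] - v[i-1]|, |v[i] - v[i+1]|)`` — strictly
    exceeds ``threshold``.  Genuine spectral features (green peak, water
    dips) vary slowly from band to band and are untouched, as are monotone
    spectra.
    """
    ms = _as_masked(s)
    if len(ms.grid) < 3:
        raise ValueError("despike needs at least 3 bands")
    v = ms.values
    left = v[1:-1] - v[:-2]
    right = v[1:-1] - v[2:]
    spike = (left > threshold) & (right > threshold)
    dip = (left < -threshold) & (right < -threshold)
    mask = ms.valid_mask.copy()
    mask[1:-1] &= ~(spike | dip)
    return MaskedSpectrum(ms.grid, ms.values, mask)


def exclude_windows(
    s: Spectrum | MaskedSpectrum, windows: ExclusionWindows | tuple = NOISY_WINDOWS_NM
) -> MaskedSpectrum:
    """Mask every band whose center lies inside any closed window (monotone)."""
    if not isinstance(windows, ExclusionWindows):
        windows = ExclusionWindows(tuple(windows))
    ms = _as_masked(s)
    mask = ms.valid_mask & ~windows.contains(ms.grid.centers)
    return MaskedSpectrum(ms.grid, ms.values, mask)


def spline_gapfill(s: MaskedSpectrum, lam: float | None = None) -> Spectrum:
    """Smoothing cubic spline through valid bands, evaluated at every center.

    ``lam`` is the roughness penalty; ``None`` selects it by generalized
    cross-validation.  With ``lam=0`` the spline interpolates the valid bands
    exactly.  Requires at least 4 valid bands.
    """
    valid = s.valid_mask
    if valid.sum() < 4:
        raise ValueError("spline_gapfill needs at least 4 valid bands")
    x = s.grid.centers[valid]
    y = s.values[valid]
    spl = make_smoothing_spline(x, y, lam=lam)
    return Spectrum(s.grid, np.asarray(spl(s.grid.centers), dtype=float))


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the per-pixel cleaning chain."""

    despike_threshold: float = DESPIKE_THRESHOLD
    windows: tuple[tuple[float, float], ...] = NOISY_WINDOWS_NM
    spline_lam: float | None = None  # None = generalized cross-validation
    smooth_valid_bands: bool = False  # False: spline only fills masked bands

    def to_dict(self) -> dict:
        return {
            "despike_threshold": self.despike_threshold,
            "windows": [list(w) for w in self.windows],
            "spline_lam": self.spline_lam,
            "smooth_valid_bands": self.smooth_valid_bands,
        }

    @staticmethod
    def from_dict(d: dict) -> "PreprocessConfig":
        return PreprocessConfig(
            despike_threshold=d.get("despike_threshold", DESPIKE_THRESHOLD),
            windows=tuple(tuple(w) for w in d.get("windows", NOISY_WINDOWS_NM)),
            spline_lam=d.get("spline_lam"),
            smooth_valid_bands=d.get("smooth_valid_bands", False),
        )


def preprocess_pixel(raw: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Full deterministic cleaning chain, ending on the harmonized band set.

    harmonized subset -> despike -> window exclusion -> spline gap filling.
    The harmonized subset comes first so that the chain is a fixed point of
    itself: a second pass sees the same grid, masks the same bands and
    reproduces the same spline.  By default the spline replaces only the
    masked bands (gap filling); set ``smooth_valid_bands`` to also smooth the
    surviving bands.
    """
    keep = harmonized_mask(raw.grid)
    sub = Spectrum(raw.grid.subset(keep), raw.values[keep])
    ms = despike(sub, cfg.despike_threshold)
    ms = exclude_windows(ms, cfg.windows)
    filled = spline_gapfill(ms, cfg.spline_lam)
    values = filled.values if cfg.smooth_valid_bands else np.where(
        ms.valid_mask, ms.values, filled.values
    )
    return Spectrum(sub.grid, values)
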