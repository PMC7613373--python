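"""Band grids, spectra containers, and Gaussian spectral-response resampling.

Wavelengths are nanometres throughout; reflectance is stored as a fraction in
[0, 1].  A :class:`BandGrid` describes a sensor's band centers and full widths
at half maximum (FWHM); fine-resolution model output (1 nm) is convolved to a
sensor grid with Gaussian spectral response functions whose standard deviation
is ``fwhm / (2 * sqrt(2 * ln 2))``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BandGrid",
    "Spectrum",
    "MaskedSpectrum",
    "CoverageError",
    "FWHM_TO_SIGMA",
    "gaussian_resample",
    "resample_matrix",
    "load_sensor_grid",
    "harmonized_mask",
    "harmonized_grid",
    "BLUE_EDGE_NM",
    "SWIR_EDGE_NM",
    "WATER_ABSORPTION_WINDOWS_NM",
]

#: FWHM of a Gaussian divided by its standard deviation (2*sqrt(2*ln2)).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Spectral-equivalence trimming applied to all data streams: bands below the
#: blue edge, above the upper SWIR edge, and inside the two broad atmospheric
#: water-vapour absorption regions are dropped before any model sees them.
BLUE_EDGE_NM = 470.0
SWIR_EDGE_NM = 2143.0
WATER_ABSORPTION_WINDOWS_NM = ((1345.0, 1510.0), (1795.0, 2000.0))


class CoverageError(ValueError):
    """A target band's support falls outside the fine-grid coverage."""


@dataclass(frozen=True)
class BandGrid:
    """Sensor band definition: strictly increasing centers with FWHM per band."""

    centers: np.ndarray
    fwhm: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        fwhm = np.asarray(self.fwhm, dtype=float)
        if centers.ndim != 1 or fwhm.shape != centers.shape:
            raise ValueError("centers and fwhm must be 1-D arrays of equal length")
        if centers.size and np.any(np.diff(centers) <= 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(fwhm <= 0):
            raise ValueError("fwhm must be positive")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "fwhm", fwhm)

    def __len__(self) -> int:
        return self.centers.size

    def subset(self, mask: np.ndarray) -> "BandGrid":
        mask = np.asarray(mask, dtype=bool)
        return BandGrid(self.centers[mask], self.fwhm[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandGrid):
            return NotImplemented
        return (
            self.centers.shape == other.centers.shape
            and np.array_equal(self.centers, other.centers)
            and np.array_equal(self.fwhm, other.fwhm)
        )

    def __hash__(self) -> int:  # frozen dataclass with arrays
        return hash((self.centers.tobytes(), self.fwhm.tobytes()))

    @staticmethod
    def fine(start: float = 400.0, stop: float = 2500.0, step: float = 1.0) -> "BandGrid":
        """Fine model grid; nominal FWHM equal to the step."""
        centers = np.arange(start, stop + 0.5 * step, step)
        return BandGrid(centers, np.full(centers.size, step))

    @staticmethod
    def from_csv(path) -> "BandGrid":
        data = np.genfromtxt(path, delimiter=",", names=True)
        return BandGrid(np.atleast_1d(data["center_nm"]), np.atleast_1d(data["fwhm_nm"]))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("center_nm,fwhm_nm\n")
            for c, w in zip(self.centers, self.fwhm):
                fh.write(f"{c:.6g},{w:.6g}\n")


@dataclass
class Spectrum:
    """Reflectance values on a :class:`BandGrid`."""

    grid: BandGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("values length must match grid")


@dataclass
class MaskedSpectrum:
    """Spectrum with a per-band validity mask; masked bands carry no meaning."""

    grid: BandGrid
    values: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(len(self.grid), dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != (len(self.grid),) or self.valid_mask.shape != self.values.shape:
            raise ValueError("values/mask length must match grid")


def resample_matrix(fine_centers: np.ndarray, target: BandGrid) -> np.ndarray:
    """Row-normalized Gaussian SRF weight matrix of shape (n_target, n_fine).

    Row ``i`` holds the spectral response of target band ``i`` sampled on the
    fine grid and normalized to unit sum, so constants are preserved exactly.
    """
    fine_centers = np.asarray(fine_centers, dtype=float)
    lo, hi = fine_centers.min(), fine_centers.max()
    if np.any(target.centers < lo) or np.any(target.centers > hi):
        raise CoverageError(
            f"target band centers fall outside the fine grid [{lo:.1f}, {hi:.1f}] nm"
        )
    sigma = target.fwhm / FWHM_TO_SIGMA
    z = (fine_centers[None, :] - target.centers[:, None]) / sigma[:, None]
    weights = np.exp(-0.5 * z * z)
    weights /= weights.sum(axis=1, keepdims=True)
    return weights


def gaussian_resample(fine: Spectrum, target: BandGrid) -> Spectrum:
    """Convolve a fine-grid spectrum to sensor bands with Gaussian SRFs."""
    weights = resample_matrix(fine.grid.centers, target)
    return Spectrum(target, weights @ fine.values)


def load_sensor_grid(name: str = "prisma_like") -> BandGrid:
    """Load a packaged nominal sensor band table.

    ``prisma_like``: a synthetic 239-band VSWIR table emulating the band count
    and spacing pattern of a PRISMA-class spectrometer (it is not the real
    instrument's table, which is not redistributable here); it is engineered so
    the standard harmonization filter retains 207 bands.
    """
    fname = {"prisma_like": "prisma_like_bands_synthetic.csv"}[name]
    ref = importlib.resources.files("cncmap.data").joinpath(fname)
    with importlib.resources.as_file(ref) as path:
        return BandGrid.from_csv(path)


def harmonized_mask(grid: BandGrid) -> np.ndarray:
    """Boolean mask of bands kept by the spectral-equivalence trimming."""
    c = grid.centers
    keep = (c >= BLUE_EDGE_NM) & (c <= SWIR_EDGE_NM)
    for lo, hi in WATER_ABSORPTION_WINDOWS_NM:
        keep &= ~((c >= lo) & (c <= hi))
    return keep


def harmonized_grid(grid: BandGrid) -> BandGrid:
    """Subset a sensor grid to the harmonized band set (idempotent)."""
    return grid.subset(harmonized_mask(grid))
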