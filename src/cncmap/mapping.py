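"""Image-wide retrieval: apply a trained bundle to cubes, map uncertainty.

A :class:`ModelBundle` packages everything needed to turn a reflectance cube
into a nitrogen map: the sensor band grid, the preprocessing configuration,
the PCA compression and the trained GP.  Per pixel the chain is
preprocess -> project -> predict; the predictive standard deviation yields a
relative-uncertainty layer (coefficient of variation, %) used as a quality
mask with the 20% climate-observation accuracy threshold by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import gpr
from .bands import BandGrid, Spectrum, harmonized_grid
from .envi import read_envi, write_envi
from .pca import PCAModel, project
from .preprocess import PreprocessConfig, preprocess_pixel

__all__ = [
    "HyperCube",
    "TraitMap",
    "ModelBundle",
    "apply_model",
    "relative_uncertainty",
    "mask_by_uncertainty",
    "CV_MASK_THRESHOLD_PCT",
]

logger = logging.getLogger(__name__)

#: Default relative-uncertainty masking threshold (%), the accuracy goal set
#: for terrestrial essential climate variables.
CV_MASK_THRESHOLD_PCT = 20.0

#: Predictive means below this (g/m^2) make the coefficient of variation
#: meaningless; such pixels are flagged invalid instead of reported infinite.
CV_MEAN_EPSILON = 1e-6


@dataclass
class HyperCube:
    """Reflectance cube (rows, cols, bands) with band grid and nodata mask."""

    values: np.ndarray
    grid: BandGrid
    nodata_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.grid):
            raise ValueError("cube must be (rows, cols, bands) matching the grid")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values).all(axis=2)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @staticmethod
    def from_envi(header_path) -> "HyperCube":
        values, grid, _ = read_envi(header_path)
        if grid is None:
            raise ValueError("ENVI header lacks wavelength/fwhm arrays")
        return HyperCube(values, grid)

    @staticmethod
    def from_hdf5(path, dataset: str = "reflectance") -> "HyperCube":
        import h5py

        with h5py.File(path, "r") as f:
            values = f[dataset][...]
            grid = BandGrid(f["wavelength_nm"][...], f["fwhm_nm"][...])
        return HyperCube(values, grid)

    def to_hdf5(self, path, dataset: str = "reflectance") -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset(dataset, data=self.values)
            f.create_dataset("wavelength_nm", data=self.grid.centers)
            f.create_dataset("fwhm_nm", data=self.grid.fwhm)


@dataclass
class TraitMap:
    """Per-pixel retrieval result: mean, SD, CV% and validity."""

    cnc_mean: np.ndarray
    cnc_sd: np.ndarray
    cv_pct: np.ndarray
    valid_mask: np.ndarray

    def masked_mean(self) -> np.ndarray:
        out = self.cnc_mean.copy()
        out[~self.valid_mask] = np.nan
        return out


@dataclass
class ModelBundle:
    """Serializable train-time state: grids, preprocessing, PCA and GP."""

    sensor_grid: BandGrid
    preprocess: PreprocessConfig
    pca: PCAModel
    gpr_model: gpr.GPRModel
    provenance: dict = field(default_factory=dict)

    @property
    def harmonized(self) -> BandGrid:
        return harmonized_grid(self.sensor_grid)

    def save(self, path) -> None:
        m = self.gpr_model
        np.savez_compressed(
            path,
            sensor_centers=self.sensor_grid.centers,
            sensor_fwhm=self.sensor_grid.fwhm,
            pca_mean=self.pca.mean_spectrum,
            pca_loadings=self.pca.loadings,
            pca_evr=self.pca.explained_variance_ratio,
            X_train=m.X_train,
            y_train=m.y_train,
            alpha=m.alpha,
            chol=m.chol_factor,
            sigma_b=m.theta.sigma_b,
            scalars=np.array([m.y_offset, m.theta.nu, m.theta.sigma_n, m.nlml]),
            meta=np.array(
                json.dumps(
                    {
                        "kernel_mode": m.kernel_mode,
                        "preprocess": self.preprocess.to_dict(),
                        "provenance": self.provenance,
                        "schema": 1,
                    }
                )
            ),
        )

    @staticmethod
    def load(path) -> "ModelBundle":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            y_offset, nu, sigma_n, nlml = z["scalars"]
            model = gpr.GPRModel(
                X_train=z["X_train"],
                y_train=z["y_train"],
                y_offset=float(y_offset),
                theta=gpr.Hyperparameters(float(nu), z["sigma_b"], float(sigma_n)),
                alpha=z["alpha"],
                chol_factor=z["chol"],
                kernel_mode=meta["kernel_mode"],
                nlml=float(nlml),
            )
            return ModelBundle(
                sensor_grid=BandGrid(z["sensor_centers"], z["sensor_fwhm"]),
                preprocess=PreprocessConfig.from_dict(meta["preprocess"]),
                pca=PCAModel(z["pca_mean"], z["pca_loadings"], z["pca_evr"]),
                gpr_model=model,
                provenance=meta["provenance"],
            )


def _pixel_features(cube: HyperCube, bundle: ModelBundle) -> np.ndarray:
    """Harmonized spectra for every pixel, flattened to (rows*cols, bands)."""
    rows, cols, _ = cube.shape
    hgrid = bundle.harmonized
    flat = cube.values.reshape(rows * cols, -1)
    if cube.grid == hgrid:
        return flat
    if cube.grid == bundle.sensor_grid:
        out = np.empty((flat.shape[0], len(hgrid)))
        for i in range(flat.shape[0]):
            out[i] = preprocess_pixel(Spectrum(cube.grid, flat[i]), bundle.preprocess).values
        return out
    raise ValueError(
        "cube band grid matches neither the bundle's sensor grid nor its "
        "harmonized grid"
    )


def apply_model(cube: HyperCube, bundle: ModelBundle, tile_size: int = 256) -> TraitMap:
    """Retrieve the trait map: preprocess, project and predict every pixel.

    Nodata pixels propagate as invalid.  Prediction runs in tiles of
    ``tile_size`` pixels purely for memory; the result is independent of the
    tiling because each pixel is an independent prediction.
    """
    rows, cols, _ = cube.shape
    npx = rows * cols
    valid = ~cube.nodata_mask.reshape(npx)
    mean = np.full(npx, np.nan)
    sd = np.full(npx, np.nan)
    if valid.any():
        feats = _pixel_features(cube, bundle)[valid]
        scores = project(bundle.pca, feats)
        idx = np.flatnonzero(valid)
        for start in range(0, idx.size, tile_size):
            sl = idx[start : start + tile_size]
            pred = gpr.predict(bundle.gpr_model, scores[start : start + tile_size])
            mean[sl] = pred.mean
            sd[sl] = np.sqrt(pred.variance)
    tmap = TraitMap(
        cnc_mean=mean.reshape(rows, cols),
        cnc_sd=sd.reshape(rows, cols),
        cv_pct=np.full((rows, cols), np.nan),
        valid_mask=valid.reshape(rows, cols),
    )
    tmap.cv_pct = relative_uncertainty(tmap)
    return tmap


def relative_uncertainty(tmap: TraitMap) -> np.ndarray:
    """Coefficient of variation 100*sd/mean (%) per pixel.

    Pixels with predictive mean below ``CV_MEAN_EPSILON`` cannot carry a
    meaningful relative uncertainty: they are flagged invalid in the map and
    receive NaN rather than an infinity in the raster.
    """
    cv = np.full(tmap.cnc_mean.shape, np.nan)
    ok = tmap.valid_mask & (tmap.cnc_mean > CV_MEAN_EPSILON)
    cv[ok] = 100.0 * tmap.cnc_sd[ok] / tmap.cnc_mean[ok]
    degenerate = tmap.valid_mask & ~ok
    if degenerate.any():
        logger.info("%d pixels with near-zero mean flagged invalid for CV", degenerate.sum())
        tmap.valid_mask = tmap.valid_mask & ok
    return cv


def mask_by_uncertainty(tmap: TraitMap, threshold_pct: float = CV_MASK_THRESHOLD_PCT) -> TraitMap:
    """Invalidate pixels whose CV exceeds the threshold (idempotent)."""
    keep = tmap.valid_mask & ~(tmap.cv_pct > threshold_pct)
    return TraitMap(tmap.cnc_mean, tmap.cnc_sd, tmap.cv_pct, keep)


def write_trait_maps(
    tmap: TraitMap, out_prefix: str, cv_threshold: float = CV_MASK_THRESHOLD_PCT
) -> list:
    """Write mean/SD/CV/masked rasters as ENVI files; returns header paths."""
    masked = mask_by_uncertainty(tmap, cv_threshold)
    paths = []
    for name, data in (
        ("cnc", tmap.cnc_mean),
        ("sd", tmap.cnc_sd),
        ("cv", tmap.cv_pct),
        ("masked", masked.masked_mean()),
    ):
        paths.append(write_envi(f"{out_prefix}_{name}", data))
    return paths
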