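"""Labeled training database: simulated canopy spectra with nitrogen labels.

Canopy nitrogen content (CNC, g/m^2) is derived from leaf protein content
(g/cm^2) and leaf area index by converting protein mass to nitrogen with the
standard protein-to-nitrogen factor 4.43 and upscaling from leaf to canopy
area::

    CNC = LAI * C_p * 10000 / 4.43

The database pairs each sampled parameter vector with its simulated
reflectance on a sensor band grid; simulation runs on the native 1 nm grid
and is convolved to sensor bands afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..bands import BandGrid, Spectrum, resample_matrix
from .optical_constants import soil_reflectance
from .prospect import prospect_pro
from .sail import sail4
from .sampling import DEFAULT_PARAMETER_SPACE, ParameterSpace, iter_param_dicts, sample_parameters

__all__ = ["PROTEIN_TO_NITROGEN", "compute_cnc", "TrainingDatabase", "build_training_database"]

#: Mass ratio of plant protein to nitrogen.
PROTEIN_TO_NITROGEN = 4.43
#: cm^2 per m^2, upscaling leaf-area-based protein to ground area.
_CM2_PER_M2 = 10000.0


def compute_cnc(lai, cp):
    """Canopy nitrogen content in g/m^2 from LAI (m^2/m^2) and C_p (g/cm^2).

    Exactly linear in each argument; raises on negative input.
    """
    lai = np.asarray(lai, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if np.any(lai < 0) or np.any(cp < 0):
        raise ValueError("LAI and C_p must be non-negative")
    out = lai * cp * _CM2_PER_M2 / PROTEIN_TO_NITROGEN
    return float(out) if out.ndim == 0 else out


@dataclass
class TrainingDatabase:
    """Paired (parameters, reflectance, CNC label) records on one band grid."""

    params: pd.DataFrame
    cnc: np.ndarray
    reflectance: np.ndarray  # (n, n_bands)
    band_grid: BandGrid
    seed: int | None
    provenance: dict

    def __len__(self) -> int:
        return len(self.cnc)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.band_grid, self.reflectance[i])

    def save(self, path) -> None:
        """Persist as a single self-describing .npz container."""
        np.savez_compressed(
            path,
            reflectance=self.reflectance,
            cnc=self.cnc,
            band_centers=self.band_grid.centers,
            band_fwhm=self.band_grid.fwhm,
            param_values=self.params.to_numpy(),
            param_names=np.array(list(self.params.columns)),
            meta=np.array(
                json.dumps({"seed": self.seed, "provenance": self.provenance})
            ),
        )

    @staticmethod
    def load(path) -> "TrainingDatabase":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            params = pd.DataFrame(z["param_values"], columns=list(z["param_names"]))
            return TrainingDatabase(
                params=params,
                cnc=z["cnc"],
                reflectance=z["reflectance"],
                band_grid=BandGrid(z["band_centers"], z["band_fwhm"]),
                seed=meta["seed"],
                provenance=meta["provenance"],
            )

    def export_csv(self, params_path, spectra_path) -> None:
        """CSV export: (parameters, CNC) table and a wavelength x sample matrix."""
        table = self.params.copy()
        table["CNC"] = self.cnc
        table.to_csv(params_path, index=False)
        spec = pd.DataFrame(
            self.reflectance.T,
            index=pd.Index(self.band_grid.centers, name="wavelength_nm"),
            columns=[f"sample_{i}" for i in range(len(self))],
        )
        spec.to_csv(spectra_path)


def simulate_sample(leaf, canopy, geom) -> np.ndarray:
    """Forward-simulate one canopy BRF spectrum on the native 1 nm grid."""
    optics = prospect_pro(leaf)
    soil = canopy.alpha_soil * soil_reflectance()
    return sail4(canopy, optics, soil, geom)


def build_training_database(
    n: int,
    band_grid: BandGrid,
    seed: int | None = None,
    noise_pct: float = 0.0,
    space: ParameterSpace = DEFAULT_PARAMETER_SPACE,
) -> TrainingDatabase:
    """Simulate ``n`` labeled canopy spectra on ``band_grid``.

    Optional additive Gaussian noise with standard deviation ``noise_pct`` %
    of each reflectance value is off by default: the workflow relies on
    sample selection rather than artificial noise to bridge the gap between
    simulation and real data.
    """
    rng = np.random.default_rng(seed)
    samples = sample_parameters(n, rng, space)
    weights = resample_matrix(np.arange(400.0, 2501.0), band_grid)
    refl = np.empty((n, len(band_grid)))
    for i, (leaf, canopy, geom) in enumerate(samples):
        refl[i] = weights @ simulate_sample(leaf, canopy, geom)
    params = pd.DataFrame(list(iter_param_dicts(samples)))
    cnc = compute_cnc(params["LAI"].to_numpy(), params["C_p"].to_numpy())
    if noise_pct > 0:
        refl = refl + rng.normal(0.0, noise_pct / 100.0 * np.abs(refl))
        refl = np.clip(refl, 0.0, 1.0)
    return TrainingDatabase(
        params=params,
        cnc=cnc,
        reflectance=refl,
        band_grid=band_grid,
        seed=seed if isinstance(seed, int) else None,
        provenance={"n": n, "noise_pct": noise_pct, "space": space.to_dict()},
    )
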