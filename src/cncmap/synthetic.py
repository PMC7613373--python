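"""Synthetic stand-ins for field campaign data, non-vegetated spectra and scenes.

The real counterparts — destructive nitrogen sampling over wheat and corn
plots, spectra picked from a satellite scene — are not publicly available,
so this module emulates their statistical structure:

* :func:`make_field_campaign` draws crop-archetype parameter trajectories
  across growth stages, simulates canopy reflectance with the same
  radiative-transfer family used for training, resamples to the sensor grid,
  subsets to the harmonized band set, and adds multiplicative spectral noise
  and additive label noise.  Because field and training spectra come from
  the same model family, this is a deliberately optimistic emulation: it
  cannot expose model-structure mismatch with real canopies.
* :func:`make_nonvegetated_library` builds smooth parametric soil / water /
  man-made endmembers on the harmonized grid.
* :func:`make_scene` lays out a patchwork of crop fields and non-vegetated
  areas with a ground-truth nitrogen raster for end-to-end mapping tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import BandGrid, harmonized_grid, load_sensor_grid, resample_matrix
from .rtm.database import compute_cnc, simulate_sample
from .rtm.optical_constants import soil_reflectance
from .rtm.prospect import LeafParams
from .rtm.sail import CanopyParams, ViewGeometry

__all__ = [
    "CampaignConfig",
    "SceneConfig",
    "make_field_campaign",
    "make_nonvegetated_library",
    "make_scene",
]

_FINE_WL = np.arange(400.0, 2501.0)


@dataclass(frozen=True)
class CampaignConfig:
    """Synthetic field-campaign settings.

    ``noise`` is the multiplicative spectral noise SD in percent (canopy
    heterogeneity plus sensor noise); ``label_noise`` the SD of the CNC
    measurement error in g/m^2.  Optional ``cnc_mean`` / ``cnc_sd`` targets
    rescale the leaf-area trajectories so the noiseless labels match given
    campaign statistics.
    """

    n_records: int = 30
    crop_archetypes: tuple[str, ...] = ("wheat", "corn")
    noise: float = 3.0
    label_noise: float = 1.0
    seed: int | None = None
    cnc_mean: float | None = None
    cnc_sd: float | None = None

    def __post_init__(self) -> None:
        if self.n_records < 2:
            raise ValueError("n_records must be >= 2")
        if self.noise < 0 or self.label_noise < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass(frozen=True)
class SceneConfig:
    """Synthetic scene layout: field patches plus non-vegetated regions."""

    rows: int = 64
    cols: int = 64
    field_patch_size: int = 8
    fraction_nonvegetated: float = 0.3
    noise: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_nonvegetated <= 1.0:
            raise ValueError("fraction_nonvegetated must be in [0, 1]")


def _stage_params(archetype: str, t: float, rng: np.random.Generator) -> tuple[LeafParams, CanopyParams]:
    """Leaf/canopy state of one crop archetype at growth stage t in [0, 1].

    Trajectories are documentation-level presets (green-up, peak, senescence),
    not calibrations to real crops; per-record jitter adds plot-to-plot
    variation.
    """
    g = np.sin(np.pi * min(max(t, 0.0), 1.0))  # green-up / senescence hump
    if archetype == "wheat":
        lai = 0.3 + 5.6 * g**1.2
        ala = 55.0
        cp = 0.0011 + 0.0009 * g
        cab = 20.0 + 45.0 * g
    elif archetype == "corn":
        lai = 0.3 + 6.2 * g**1.4
        ala = 62.0
        cp = 0.0012 + 0.0010 * g
        cab = 25.0 + 50.0 * g
    else:
        raise ValueError(f"unknown crop archetype {archetype!r}")
    jit = rng.normal(0.0, 1.0, 8)
    lai = float(np.clip(lai * np.exp(0.12 * jit[0]), 0.1, 7.0))
    cp = float(np.clip(cp * (1.0 + 0.08 * jit[1]), 0.001, 0.0025))
    cab = float(np.clip(cab + 5.0 * jit[2], 0.0, 80.0))
    leaf = LeafParams(
        N_struct=float(np.clip(1.5 + 0.15 * jit[3], 1.0, 2.5)),
        C_ab=cab,
        C_xc=float(np.clip(cab * 0.22, 0.0, 15.0)),
        C_anth=float(np.clip(0.5 + 0.3 * jit[4], 0.0, 2.0)),
        C_w=float(np.clip(0.004 + 0.011 * g + 0.002 * jit[5], 0.001, 0.02)),
        C_p=cp,
        CBC=float(np.clip(0.002 + 0.005 * t + 0.001 * jit[6], 0.001, 0.01)),
    )
    canopy = CanopyParams(
        LAI=lai,
        ALA=float(np.clip(ala + 3.0 * jit[7], 30.0, 70.0)),
        HotS=0.1,
        alpha_soil=float(rng.uniform(0.3, 1.0)),
    )
    return leaf, canopy


def make_field_campaign(
    cfg: CampaignConfig, sensor_grid: BandGrid | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Synthetic campaign: (spectra on the harmonized grid, noisy CNC, truth).

    The truth table holds the generating parameters and the noise-free label
    of every record; labels are computed from leaf area and protein content
    before measurement noise is added, and noisy labels are floored at zero.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = sensor_grid or load_sensor_grid()
    hgrid = harmonized_grid(grid)
    weights = resample_matrix(_FINE_WL, hgrid)
    geom = ViewGeometry()

    states = []
    for i in range(cfg.n_records):
        archetype = cfg.crop_archetypes[i % len(cfg.crop_archetypes)]
        t = rng.uniform(0.05, 0.95)
        leaf, canopy = _stage_params(archetype, t, rng)
        states.append((archetype, t, leaf, canopy))

    cnc_true = np.array([compute_cnc(c.LAI, l.C_p) for _, _, l, c in states])
    if cfg.cnc_mean is not None:
        target_sd = cfg.cnc_sd if cfg.cnc_sd is not None else cnc_true.std()
        z = (cnc_true - cnc_true.mean()) / max(cnc_true.std(), 1e-9)
        desired = cfg.cnc_mean + target_sd * z
        # CNC is linear in LAI, so retargeting adjusts the leaf-area axis.
        states = [
            (
                a,
                t,
                l,
                CanopyParams(
                    LAI=float(np.clip(d * 4.43 / 1e4 / l.C_p, 0.1, 7.0)),
                    ALA=c.ALA,
                    HotS=c.HotS,
                    alpha_soil=c.alpha_soil,
                ),
            )
            for (a, t, l, c), d in zip(states, desired)
        ]
        cnc_true = np.array([compute_cnc(c.LAI, l.C_p) for _, _, l, c in states])

    spectra = np.empty((cfg.n_records, len(hgrid)))
    for i, (_, _, leaf, canopy) in enumerate(states):
        spectra[i] = weights @ simulate_sample(leaf, canopy, geom)
    if cfg.noise > 0:
        spectra = np.clip(
            spectra * (1.0 + rng.normal(0.0, cfg.noise / 100.0, spectra.shape)), 0.0, 1.0
        )
    labels = cnc_true.copy()
    if cfg.label_noise > 0:
        labels = np.clip(labels + rng.normal(0.0, cfg.label_noise, labels.size), 0.0, None)

    truth = pd.DataFrame(
        {
            "archetype": [a for a, _, _, _ in states],
            "stage": [t for _, t, _, _ in states],
            "LAI": [c.LAI for _, _, _, c in states],
            "C_p": [l.C_p for _, _, l, _ in states],
            "cnc_true": cnc_true,
            "cnc_measured": labels,
        }
    )
    return spectra, labels, truth


def make_nonvegetated_library(
    k: int = 24, seed: int | None = None, grid: BandGrid | None = None
) -> np.ndarray:
    """``k`` smooth non-vegetated endmembers on the harmonized band grid.

    Archetypes cycle through scaled bare soil, dark water-like curves
    (NIR/SWIR reflectance below 0.05) and sloped bright man-made surfaces;
    small smooth perturbations keep the spectra pairwise distinct.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    hgrid = harmonized_grid(grid or load_sensor_grid())
    wl = hgrid.centers
    u = (wl - wl[0]) / (wl[-1] - wl[0])  # normalized wavelength in [0, 1]
    soil_h = resample_matrix(_FINE_WL, hgrid) @ soil_reflectance()

    out = np.empty((k, len(hgrid)))
    for i in range(k):
        kind = ("soil", "water", "manmade")[i % 3]
        smooth_pert = (
            rng.normal(0.0, 0.01) * np.polynomial.legendre.legval(2.0 * u - 1.0, [0, 1])
            + rng.normal(0.0, 0.008) * np.polynomial.legendre.legval(2.0 * u - 1.0, [0, 0, 1])
        )
        if kind == "soil":
            s = rng.uniform(0.5, 1.2) * soil_h + smooth_pert
        elif kind == "water":
            s = 0.012 + rng.uniform(0.015, 0.03) * np.exp(-u / rng.uniform(0.08, 0.15))
            s = s + 0.3 * smooth_pert * np.exp(-u / 0.2)
        else:  # man-made: bright, gently sloped
            s = rng.uniform(0.12, 0.32) + rng.uniform(-0.04, 0.18) * u + smooth_pert
        out[i] = np.clip(s, 0.001, 0.95)
    return out


def make_scene(cfg: SceneConfig, sensor_grid: BandGrid | None = None):
    """Synthetic ground-truthed scene on the harmonized grid.

    Returns ``(cube_values, truth_cnc, hgrid)`` where ``cube_values`` has
    shape (rows, cols, bands) and ``truth_cnc`` holds 0 on non-vegetated
    pixels.  Fields are rectangular patches with one canopy state per field
    and lognormal within-field leaf-area variation.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = sensor_grid or load_sensor_grid()
    hgrid = harmonized_grid(grid)
    weights = resample_matrix(_FINE_WL, hgrid)
    geom = ViewGeometry()
    nv_lib = make_nonvegetated_library(12, seed=rng.integers(2**31), grid=grid)

    values = np.empty((cfg.rows, cfg.cols, len(hgrid)))
    truth = np.zeros((cfg.rows, cfg.cols))
    ps = cfg.field_patch_size
    for r0 in range(0, cfg.rows, ps):
        for c0 in range(0, cfg.cols, ps):
            r1, c1 = min(r0 + ps, cfg.rows), min(c0 + ps, cfg.cols)
            if rng.uniform() < cfg.fraction_nonvegetated:
                base = nv_lib[rng.integers(len(nv_lib))]
                for r in range(r0, r1):
                    for c in range(c0, c1):
                        values[r, c] = base
            else:
                archetype = ("wheat", "corn")[int(rng.integers(2))]
                t = rng.uniform(0.05, 0.95)
                leaf, canopy = _stage_params(archetype, t, rng)
                for r in range(r0, r1):
                    for c in range(c0, c1):
                        lai_px = float(np.clip(canopy.LAI * np.exp(rng.normal(0.0, 0.1)), 0.1, 7.0))
                        px_canopy = CanopyParams(lai_px, canopy.ALA, canopy.HotS, canopy.alpha_soil)
                        values[r, c] = weights @ simulate_sample(leaf, px_canopy, geom)
                        truth[r, c] = compute_cnc(lai_px, leaf.C_p)
    if cfg.noise > 0:
        values = np.clip(values * (1.0 + rng.normal(0.0, cfg.noise / 100.0, values.shape)), 0.0, 1.0)
    return values, truth, hgrid
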