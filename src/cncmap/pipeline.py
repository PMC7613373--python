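"""Orchestration: train, evaluate and map from a single configuration.

``train_pipeline`` runs the full hybrid workflow: simulate the labeled
training database, compress it with PCA, optimize the sample set with
diversity active learning against a validation set, append non-vegetated
spectra, fit the final ARD Gaussian process, and report validation metrics.
Every stage is seeded, and a frozen config snapshot travels with the bundle.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import gpr
from .activelearning import ALResult, LabeledPool, ValidationSet, augment_nonvegetated, run_ebd_al
from .bands import BandGrid, harmonized_grid, load_sensor_grid
from .mapping import CV_MASK_THRESHOLD_PCT, ModelBundle
from .pca import fit_pca, project
from .preprocess import PreprocessConfig
from .rtm.database import build_training_database
from .rtm.sampling import DEFAULT_PARAMETER_SPACE, ParameterSpace
from .synthetic import CampaignConfig, make_field_campaign

__all__ = ["PipelineConfig", "train_pipeline", "evaluate"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Whole-workflow configuration with the study defaults."""

    n_simulations: int = 1000
    noise_pct: float = 0.0
    n_components: int = 20
    al_enabled: bool = True
    init_frac: float = 0.10
    al_kernel_mode: str = "isotropic"
    al_max_iterations: int | None = None
    nv_enabled: bool = True
    nv_count: int = 24
    final_kernel_mode: str = "ard"
    final_restarts: int = 5
    cv_threshold_pct: float = CV_MASK_THRESHOLD_PCT
    seed: int = 0
    sensor: str = "prisma_like"
    parameter_space: dict = field(default_factory=lambda: DEFAULT_PARAMETER_SPACE.to_dict())
    preprocess: dict = field(default_factory=lambda: PreprocessConfig().to_dict())

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig(**(yaml.safe_load(fh) or {}))


def train_pipeline(
    cfg: PipelineConfig,
    validation_spectra: np.ndarray | None = None,
    validation_cnc: np.ndarray | None = None,
    nv_spectra: np.ndarray | None = None,
    sensor_grid: BandGrid | None = None,
) -> tuple[ModelBundle, ALResult | None, gpr.FitMetrics]:
    """Train the full retrieval bundle; returns (bundle, AL result, metrics).

    When no validation records are supplied a synthetic field campaign is
    generated (the stand-in for unpublished destructive sampling); when no
    non-vegetated spectra are supplied and NV augmentation is enabled, a
    synthetic library is generated.
    """
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    grid = sensor_grid or load_sensor_grid(cfg.sensor)
    hgrid = harmonized_grid(grid)
    space = ParameterSpace.from_dict(cfg.parameter_space)
    pre_cfg = PreprocessConfig.from_dict(cfg.preprocess)

    logger.info("stage=simulate n=%d", cfg.n_simulations)
    db = build_training_database(
        cfg.n_simulations, hgrid, seed=int(rng.integers(2**31)),
        noise_pct=cfg.noise_pct, space=space,
    )

    if validation_spectra is None:
        logger.info("stage=synthetic-campaign")
        validation_spectra, validation_cnc, _ = make_field_campaign(
            CampaignConfig(seed=int(rng.integers(2**31))), sensor_grid=grid
        )
    validation_spectra = np.atleast_2d(np.asarray(validation_spectra, dtype=float))
    validation_cnc = np.asarray(validation_cnc, dtype=float)

    logger.info("stage=pca k=%d", cfg.n_components)
    pca = fit_pca(db.reflectance, cfg.n_components)
    pool = LabeledPool(project(pca, db.reflectance), db.cnc)
    val = ValidationSet(project(pca, validation_spectra), validation_cnc)

    al_result = None
    if cfg.al_enabled:
        logger.info("stage=active-learning init_frac=%.2f", cfg.init_frac)
        al_result, _ = run_ebd_al(
            pool,
            val,
            init_frac=cfg.init_frac,
            seed=int(rng.integers(2**31)),
            kernel_mode=cfg.al_kernel_mode,
            max_iterations=cfg.al_max_iterations,
        )
        sel = np.asarray(
            [int(i) for i in al_result.selected_ids], dtype=int
        )
        training = LabeledPool(pool.scores[sel], pool.labels[sel], pool.ids[sel])
    else:
        training = pool

    if cfg.nv_enabled:
        if nv_spectra is None:
            from .synthetic import make_nonvegetated_library

            nv_spectra = make_nonvegetated_library(
                cfg.nv_count, seed=int(rng.integers(2**31)), grid=grid
            )
        logger.info("stage=nv-augmentation count=%d", len(nv_spectra))
        training = augment_nonvegetated(training, nv_spectra, pca)

    logger.info("stage=final-fit kernel=%s n=%d", cfg.final_kernel_mode, len(training))
    final = gpr.fit(
        training.scores,
        training.labels,
        kernel_mode=cfg.final_kernel_mode,
        n_restarts=cfg.final_restarts,
        seed=int(rng.integers(2**31)),
    )
    bundle = ModelBundle(
        sensor_grid=grid,
        preprocess=pre_cfg,
        pca=pca,
        gpr_model=final,
        provenance={
            "config": asdict(cfg),
            "training_size": len(training),
            "al_final_size": None if al_result is None else al_result.final_size,
            "wall_time_s": round(time.time() - t0, 2),
        },
    )
    pred = gpr.predict(final, val.scores)
    metrics = gpr.goodness_of_fit(pred.mean, val.cnc_measured)
    logger.info(
        "stage=done rmse=%.3f nrmse=%.2f%% r2=%.3f n_train=%d",
        metrics.rmse, metrics.nrmse, metrics.r2, len(training),
    )
    return bundle, al_result, metrics


def evaluate(
    bundle: ModelBundle, validation_spectra: np.ndarray, validation_cnc: np.ndarray
) -> tuple[gpr.FitMetrics, dict]:
    """Per-record predictions with uncertainty plus pooled metrics.

    The returned scatter dictionary (observed, predicted, sd) supports
    measured-versus-estimated plots along the 1:1 line.
    """
    scores = project(bundle.pca, np.atleast_2d(validation_spectra))
    pred = gpr.predict(bundle.gpr_model, scores)
    observed = np.asarray(validation_cnc, dtype=float)
    metrics = gpr.goodness_of_fit(pred.mean, observed)
    scatter = {
        "observed": observed,
        "predicted": pred.mean,
        "sd": np.sqrt(pred.variance),
    }
    return metrics, scatter
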