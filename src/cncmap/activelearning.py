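"""Diversity-based active learning over a labeled simulation pool.

Euclidean-distance-based diversity (EBD) selection: starting from a random
10% of the pool, the candidate whose squared Euclidean distance to the
current training set is largest (maximin criterion) is tentatively added;
the regressor is refit and the candidate is kept only if the root mean
square error against an external validation set strictly decreases.  Every
pool sample is evaluated exactly once, so the recorded RMSE trace is
strictly decreasing at accepted steps and the final model never validates
worse than the initial one.

Training happens in the compressed principal-component space; a small
library of non-vegetated spectra (label 0 g/m^2) can be appended afterwards
so the final model copes with heterogeneous scenes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import gpr
from .pca import PCAModel, project

__all__ = [
    "LabeledPool",
    "ValidationSet",
    "ALResult",
    "ebd_distance",
    "select_next",
    "run_ebd_al",
    "augment_nonvegetated",
]

logger = logging.getLogger(__name__)


@dataclass
class LabeledPool:
    """Row-aligned PC scores, CNC labels and stable sample identifiers."""

    scores: np.ndarray  # (n, k)
    labels: np.ndarray  # g/m^2
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.labels = np.asarray(self.labels, dtype=float)
        if self.ids is None:
            self.ids = np.arange(self.scores.shape[0])
        self.ids = np.asarray(self.ids)
        if not (self.scores.shape[0] == self.labels.size == self.ids.size):
            raise ValueError("scores, labels and ids must be row-aligned")

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class ValidationSet:
    """Preprocessed, PCA-projected field records with measured CNC."""

    scores: np.ndarray
    cnc_measured: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.cnc_measured = np.asarray(self.cnc_measured, dtype=float)
        if self.scores.shape[0] != self.cnc_measured.size or self.cnc_measured.size < 2:
            raise ValueError("validation needs >= 2 row-aligned records")


@dataclass
class ALResult:
    """Accepted sample ids plus the per-subset goodness-of-fit trace."""

    selected_ids: np.ndarray
    trace: pd.DataFrame  # columns: size, rmse, r2
    seed: int | None
    config: dict

    @property
    def final_size(self) -> int:
        return int(self.selected_ids.size)

    def to_json_dict(self) -> dict:
        return {
            "selected_ids": self.selected_ids.tolist(),
            "trace": self.trace.to_dict(orient="list"),
            "seed": self.seed,
            "config": self.config,
        }


def ebd_distance(candidate: np.ndarray, training: np.ndarray, aggregate: str = "min") -> float:
    """Squared-Euclidean remoteness of a candidate from the training set.

    ``min`` (default) is the maximin diversity criterion: the distance to the
    nearest training sample, zero iff the candidate duplicates one.  ``mean``
    and ``sum`` aggregations are available for comparison.
    """
    candidate = np.asarray(candidate, dtype=float).reshape(1, -1)
    training = np.atleast_2d(np.asarray(training, dtype=float))
    if training.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    if training.shape[1] != candidate.shape[1]:
        raise ValueError("dimension mismatch between candidate and training set")
    d2 = cdist(candidate, training, metric="sqeuclidean")[0]
    if aggregate == "min":
        return float(d2.min())
    if aggregate == "mean":
        return float(d2.mean())
    if aggregate == "sum":
        return float(d2.sum())
    raise ValueError(f"unknown aggregate {aggregate!r}")


def select_next(
    pool_scores: np.ndarray,
    pool_ids: np.ndarray,
    training_scores: np.ndarray,
    aggregate: str = "min",
) -> int:
    """Index (into the remaining pool) of the most remote candidate.

    Ties are broken by the smallest sample id for reproducibility.
    """
    pool_scores = np.atleast_2d(pool_scores)
    if pool_scores.shape[0] == 0:
        raise ValueError("remaining pool is empty")
    d2 = cdist(pool_scores, np.atleast_2d(training_scores), metric="sqeuclidean")
    agg = {"min": d2.min, "mean": d2.mean, "sum": d2.sum}[aggregate](axis=1)
    best = np.flatnonzero(agg == agg.max())
    return int(best[np.argmin(np.asarray(pool_ids)[best])])


def run_ebd_al(
    pool: LabeledPool,
    val: ValidationSet,
    init_frac: float = 0.10,
    seed: int | None = None,
    kernel_mode: str = "isotropic",
    aggregate: str = "min",
    max_iterations: int | None = None,
    n_restarts_initial: int = 3,
    maxiter_inner: int = 40,
) -> tuple[ALResult, gpr.GPRModel]:
    """Single-pass EBD active learning with validation-RMSE acceptance.

    Returns the result trace and the model fit on the final selection (with
    the inner, warm-started kernel mode).  Candidates whose refit fails are
    skipped with a logged warning.
    """
    if len(pool) < 10:
        raise ValueError("pool must hold at least 10 samples")
    rng = np.random.default_rng(seed)
    n_init = int(np.floor(init_frac * len(pool)))
    if n_init < 2:
        raise ValueError("initial fraction selects fewer than 2 samples")
    order = rng.permutation(len(pool))
    selected = list(order[:n_init])
    remaining = list(order[n_init:])
    if max_iterations is not None:
        remaining = remaining[: int(max_iterations)]

    model = gpr.fit(
        pool.scores[selected],
        pool.labels[selected],
        kernel_mode=kernel_mode,
        n_restarts=n_restarts_initial,
        seed=rng,
    )
    pred = gpr.predict(model, val.scores)
    metrics = gpr.goodness_of_fit(pred.mean, val.cnc_measured)
    rows = [(len(selected), metrics.rmse, metrics.r2)]
    best_rmse = metrics.rmse

    while remaining:
        rel = select_next(
            pool.scores[remaining], pool.ids[remaining], pool.scores[selected], aggregate
        )
        cand = remaining.pop(rel)
        trial = selected + [cand]
        try:
            trial_model = gpr.fit(
                pool.scores[trial],
                pool.labels[trial],
                kernel_mode=kernel_mode,
                n_restarts=1,
                seed=rng,
                theta0=model.theta,
                maxiter=maxiter_inner,
            )
        except (RuntimeError, np.linalg.LinAlgError) as err:
            logger.warning("refit failed for candidate id %s: %s", pool.ids[cand], err)
            continue
        pred = gpr.predict(trial_model, val.scores)
        metrics = gpr.goodness_of_fit(pred.mean, val.cnc_measured)
        if metrics.rmse < best_rmse:
            selected = trial
            model = trial_model
            best_rmse = metrics.rmse
            rows.append((len(selected), metrics.rmse, metrics.r2))

    trace = pd.DataFrame(rows, columns=["size", "rmse", "r2"])
    result = ALResult(
        selected_ids=pool.ids[selected],
        trace=trace,
        seed=seed,
        config={
            "init_frac": init_frac,
            "kernel_mode": kernel_mode,
            "aggregate": aggregate,
            "max_iterations": max_iterations,
        },
    )
    return result, model


def augment_nonvegetated(
    pool: LabeledPool, nv_spectra: np.ndarray, pca: PCAModel
) -> LabeledPool:
    """Append non-vegetated spectra (label 0 g/m^2) projected through the PCA.

    The spectra must be on the harmonized band grid the PCA was fit on; the
    existing model is reused without refitting.  Non-vegetated surfaces carry
    no canopy nitrogen, hence the zero label.
    """
    nv_spectra = np.atleast_2d(np.asarray(nv_spectra, dtype=float))
    if nv_spectra.shape[0] == 0:
        return pool
    nv_scores = project(pca, nv_spectra)
    nv_ids = np.array([f"nv_{i}" for i in range(nv_spectra.shape[0])], dtype=object)
    ids = np.concatenate([np.asarray(pool.ids, dtype=object), nv_ids])
    return LabeledPool(
        scores=np.vstack([pool.scores, nv_scores]),
        labels=np.concatenate([pool.labels, np.zeros(nv_spectra.shape[0])]),
        ids=ids,
    )
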