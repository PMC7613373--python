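"""Spectral compression with centered principal component analysis.

Hyperspectral reflectance bands are strongly collinear; a kernel regressor
fed with raw bands wastes capacity on redundant directions and is sensitive
to band noise.  The workflow therefore compresses spectra to 20 principal
components fit once on the simulated training database and reused unchanged
for validation spectra, non-vegetated spectra and image pixels.  Bands share
units and scale, so the PCA centers but does not rescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

__all__ = ["PCAModel", "fit_pca", "project", "cumulative_variance"]


@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings and explained-variance shares."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_components, n_bands), rows orthonormal
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(X: np.ndarray, k: int = 20) -> PCAModel:
    """Centered PCA of a (samples x bands) matrix, components by variance.

    If the matrix rank is below ``k`` only the available components are
    retained, with a warning.  Component signs are fixed by making the
    largest-magnitude loading entry positive, for reproducible serialization.
    """
    X = np.asarray(X, dtype=float)
    n, b = X.shape
    if n < k or b < k:
        raise ValueError(f"need at least k={k} samples and bands, got {X.shape}")
    sk = _SkPCA(n_components=k, svd_solver="full")
    sk.fit(X)
    loadings = sk.components_.copy()
    ratios = sk.explained_variance_ratio_.copy()
    # Drop numerically null directions of rank-deficient data.
    tol = max(n, b) * np.finfo(float).eps * max(sk.singular_values_.max(), 1.0)
    nz = sk.singular_values_ > tol
    if nz.sum() < k:
        warnings.warn(
            f"data rank {int(nz.sum())} below requested {k} components; "
            "retaining available components",
            stacklevel=2,
        )
        loadings, ratios = loadings[nz], ratios[nz]
    flip = np.sign(loadings[np.arange(loadings.shape[0]), np.argmax(np.abs(loadings), axis=1)])
    loadings *= flip[:, None]
    return PCAModel(sk.mean_.copy(), loadings, ratios)


def project(model: PCAModel, spectra: np.ndarray) -> np.ndarray:
    """Scores ``loadings @ (spectrum - mean)`` for one spectrum or a matrix."""
    spectra = np.asarray(spectra, dtype=float)
    single = spectra.ndim == 1
    mat = np.atleast_2d(spectra)
    if mat.shape[1] != model.mean_spectrum.size:
        raise ValueError(
            f"spectra have {mat.shape[1]} bands, model expects {model.mean_spectrum.size}"
        )
    scores = (mat - model.mean_spectrum) @ model.loadings.T
    return scores[0] if single else scores


def cumulative_variance(model: PCAModel, j: int) -> float:
    """Cumulative explained-variance fraction of the first ``j`` components."""
    if not 1 <= j <= model.n_components:
        raise ValueError(f"j must be in [1, {model.n_components}]")
    return float(model.explained_variance_ratio[:j].sum())
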