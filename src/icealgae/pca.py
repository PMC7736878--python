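"""Unsupervised exploration of pooled pixel spectra with mean-centred PCA.

Valid pixels from all cubes of one scan geometry are pooled into a
single sample matrix so principal-component scores are comparable across
cores. On transmitted-light imagery of translucent columnar ice, PC1
loadings take the shape of the lamp spectrum (a transmitted-intensity
proxy) while PC2 loadings mirror the chlorophyll-a absorption spectrum,
making per-pixel PC2 score maps a normalisation-free biomass proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .cube import SpectralCube


@dataclass
class PixelPool:
    """Pooled valid-pixel spectra with row-level provenance."""

    matrix: np.ndarray  # (n_pixels, n_bands)
    provenance: np.ndarray  # (n_pixels, 3) of (cube_index, line, sample)
    wavelengths: np.ndarray
    group: str | None = None


@dataclass
class PCAModel:
    """Mean-centred PCA of a pixel pool: band means, loadings, variance."""

    band_means: np.ndarray
    loadings: np.ndarray  # (components, bands), orthonormal rows
    explained_variance_ratio: np.ndarray
    wavelengths: np.ndarray


def pool_pixels(
    cubes: list[SpectralCube],
    group: str | None = None,
    subsample: int | None = None,
    seed: int = 0,
) -> PixelPool:
    """Pool valid pixels of several cubes into one sample matrix.

    With *group* set, only cubes whose ``meta['group']`` matches are
    admitted — vertical and horizontal scans are never mixed in one pool.
    A seeded uniform subsample caps memory on large pools.
    """
    if not cubes:
        raise ValueError("no cubes to pool")
    wavelengths = cubes[0].wavelengths
    rows, prov = [], []
    for i, cube in enumerate(cubes):
        if not np.array_equal(cube.wavelengths, wavelengths):
            raise ValueError("all pooled cubes must share one wavelength grid")
        if group is not None and cube.meta.get("group") != group:
            raise ValueError(
                f"cube {i} has group {cube.meta.get('group')!r}, pool wants {group!r}"
            )
        lines, samples = np.nonzero(cube.mask)
        rows.append(cube.data[lines, samples])
        prov.append(np.column_stack([np.full(lines.size, i), lines, samples]))
    matrix = np.concatenate(rows, axis=0)
    provenance = np.concatenate(prov, axis=0)
    if subsample is not None and subsample < matrix.shape[0]:
        idx = np.random.default_rng(seed).choice(
            matrix.shape[0], size=subsample, replace=False)
        idx.sort()
        matrix, provenance = matrix[idx], provenance[idx]
    return PixelPool(matrix, provenance, wavelengths, group)


def fit_pca(pool: PixelPool, n_components: int = 2) -> PCAModel:
    """Covariance PCA of mean-centred pooled spectra (deterministic SVD).

    No band scaling is applied. The sign of each component is fixed so
    its largest-magnitude loading element is positive, making loadings
    reproducible across runs and solvers.
    """
    n_pixels = pool.matrix.shape[0]
    if n_pixels <= n_components:
        raise ValueError(
            f"need more than {n_components} pixels to fit {n_components} components"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    model.fit(pool.matrix)
    loadings = model.components_.copy()
    for k in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
    return PCAModel(model.mean_, loadings,
                    model.explained_variance_ratio_, pool.wavelengths)


def score_maps(cube: SpectralCube, model: PCAModel,
               components: list[int] | None = None) -> np.ndarray:
    """Per-pixel projections onto the requested components.

    Returns an array of shape (n_requested, lines, samples); masked-out
    pixels are NaN.
    """
    if not np.array_equal(cube.wavelengths, model.wavelengths):
        raise ValueError("cube and PCA model wavelength grids must agree")
    if components is None:
        components = list(range(model.loadings.shape[0]))
    for c in components:
        if not 0 <= c < model.loadings.shape[0]:
            raise ValueError(f"component index {c} out of range")
    centred = cube.data - model.band_means[None, None, :]
    scores = np.tensordot(centred, model.loadings[components].T, axes=([2], [0]))
    scores = np.moveaxis(scores, 2, 0)
    scores[:, ~cube.mask] = np.nan
    return scores
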