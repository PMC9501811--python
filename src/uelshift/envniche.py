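"""Environmental-space niche quantification.

The global climatic niche of a species is described in the plane of the
first two principal components of the scaled climate variables, computed on
a global background sample of available climates. Occurrence and background
densities are estimated by Gaussian kernel smoothing on an R x R lattice
over that plane, and the niche region is the smallest set of densest cells
holding a given fraction (default 99%) of the occurrence density mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PCASpace:
    """Centering/scaling constants and the first two principal axes."""

    variables: tuple[str, ...]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray          # (n_vars, 2), orthonormal columns
    explained_variance: np.ndarray  # fraction per retained axis


@dataclass(frozen=True)
class EnvGrid:
    """Gridded environmental space with occurrence and background densities.

    Each density is non-negative and sums to 1 over the lattice. ``x_edges``
    and ``y_edges`` have length R+1 and cover all calibration scores.
    """

    resolution: int
    x_edges: np.ndarray
    y_edges: np.ndarray
    occ_density: np.ndarray  # (R, R), rows = x cells, cols = y cells
    bg_density: np.ndarray

    @property
    def cell_area(self) -> float:
        return float((self.x_edges[1] - self.x_edges[0])
                     * (self.y_edges[1] - self.y_edges[0]))


@dataclass(frozen=True)
class NicheRegion:
    """Boolean mask of grid cells forming the delineated niche."""

    mask: np.ndarray
    level: float


class SpeciesSkipped(Exception):
    """Raised when a species has too few occurrences to build a niche."""


def _validate_matrix(data: pd.DataFrame, variables: list[str]) -> np.ndarray:
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise ValueError(f"samples lack calibration variables: {missing}")
    x = data[variables].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(x).all(axis=1))
    if bad.size:
        raise ValueError(f"missing/non-finite climate values in rows {bad[:10].tolist()}")
    return x


def fit_pca(background: pd.DataFrame, variables: list[str] | None = None) -> PCASpace:
    """Calibrate the environmental space on the global background.

    Variables are centred and scaled to unit variance (population SD, as in
    ade4's dudi.pca), then the first two axes are extracted by SVD. The
    sign of each axis is fixed so that its largest-magnitude loading is
    positive.
    """
    if variables is None:
        variables = [c for c in background.columns if c.startswith("bio")]
    if len(variables) < 2:
        raise ValueError("need at least 2 climate variables")
    if len(background) < 3:
        raise ValueError("need at least 3 background samples")
    x = _validate_matrix(background, variables)
    means = x.mean(axis=0)
    scales = x.std(axis=0, ddof=0)
    constant = np.flatnonzero(scales == 0)
    if constant.size:
        names = [variables[i] for i in constant]
        raise ValueError(f"constant climate variable(s): {names}")
    z = (x - means) / scales
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:2].T
    # sign convention: largest |loading| positive per axis
    for j in range(2):
        k = np.argmax(np.abs(loadings[:, j]))
        if loadings[k, j] < 0:
            loadings[:, j] = -loadings[:, j]
    var = svals**2 / np.sum(svals**2)
    return PCASpace(variables=tuple(variables), means=means, scales=scales,
                    loadings=loadings, explained_variance=var[:2])


def project(pca: PCASpace, samples: pd.DataFrame) -> np.ndarray:
    """Project samples onto axes 1-2 of the calibrated space."""
    x = _validate_matrix(samples, list(pca.variables))
    return (x - pca.means) / pca.scales @ pca.loadings


def _scott_bandwidth(scores: np.ndarray, fallback: np.ndarray | None = None) -> np.ndarray:
    """Scott's rule per axis for a 2-D diagonal Gaussian kernel.

    A degenerate axis (zero spread, e.g. all occurrences in one cell) falls
    back to ``fallback`` — typically one grid-cell width — so the kernel
    still deposits mass on the lattice.
    """
    n = scores.shape[0]
    sd = scores.std(axis=0, ddof=1) if n > 1 else np.zeros(scores.shape[1])
    bw = sd * n ** (-1.0 / 6.0)
    if fallback is None:
        fallback = np.full_like(bw, 1e-6)
    return np.where(bw > 0, bw, fallback)


def _kde_on_lattice(scores: np.ndarray, bw: np.ndarray,
                    x_centers: np.ndarray, y_centers: np.ndarray) -> np.ndarray:
    """Diagonal-bandwidth Gaussian KDE evaluated on a lattice.

    Separability of the kernel lets the (R x R) surface be a product of two
    (R x n) kernel matrices, avoiding the R^2 x n tensor.
    """
    gx = np.exp(-0.5 * ((x_centers[:, None] - scores[None, :, 0]) / bw[0]) ** 2)
    gy = np.exp(-0.5 * ((y_centers[:, None] - scores[None, :, 1]) / bw[1]) ** 2)
    dens = gx @ gy.T
    total = dens.sum()
    if total <= 0:
        raise ValueError("degenerate density: no mass on the lattice")
    return dens / total


def build_grid(pca: PCASpace, background_scores: np.ndarray,
               occurrence_scores: np.ndarray, resolution: int = 100,
               min_occurrences: int = 5) -> EnvGrid:
    """Grid the environmental plane and estimate both densities.

    Axis ranges are the calibration (background) score range padded by the
    occurrence bandwidth, so occurrence mass near the envelope edge is not
    truncated. Raises :class:`SpeciesSkipped` when there are fewer than
    ``min_occurrences`` occurrence points.
    """
    occurrence_scores = np.atleast_2d(occurrence_scores)
    if occurrence_scores.shape[0] < min_occurrences:
        logger.warning("species skipped: %d occurrences < minimum %d",
                       occurrence_scores.shape[0], min_occurrences)
        raise SpeciesSkipped(
            f"{occurrence_scores.shape[0]} occurrences < minimum {min_occurrences}")
    cell = (background_scores.max(axis=0) - background_scores.min(axis=0)) / resolution
    bw = _scott_bandwidth(occurrence_scores, fallback=cell)
    lo = background_scores.min(axis=0) - bw
    hi = background_scores.max(axis=0) + bw
    x_edges = np.linspace(lo[0], hi[0], resolution + 1)
    y_edges = np.linspace(lo[1], hi[1], resolution + 1)
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    occ = _kde_on_lattice(occurrence_scores, bw, xc, yc)
    bg = _kde_on_lattice(background_scores,
                         _scott_bandwidth(background_scores, fallback=cell), xc, yc)
    return EnvGrid(resolution=resolution, x_edges=x_edges, y_edges=y_edges,
                   occ_density=occ, bg_density=bg)


def delineate_niche(grid: EnvGrid, level: float = 0.99,
                    background_corrected: bool = False) -> NicheRegion:
    """Select the densest cells holding ``level`` of the occurrence mass.

    Cells are ranked by occurrence density (optionally divided by
    background availability) and included until the cumulative occurrence
    mass reaches ``level``; cells tied with the last included density are
    all included.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError("level must be in (0, 1]")
    density = grid.occ_density
    if background_corrected:
        with np.errstate(divide="ignore", invalid="ignore"):
            rank_by = np.where(grid.bg_density > 0, density / grid.bg_density, 0.0)
    else:
        rank_by = density
    flat_rank = rank_by.ravel()
    flat_mass = density.ravel()
    order = np.argsort(flat_rank)[::-1]
    cum = np.cumsum(flat_mass[order])
    n_take = int(np.searchsorted(cum, level - 1e-12) + 1)
    n_take = min(n_take, order.size)
    cutoff = flat_rank[order[n_take - 1]]
    mask = (rank_by >= cutoff) & (density > 0) if cutoff > 0 else rank_by >= cutoff
    if level >= 1.0:
        mask = density > 0
    return NicheRegion(mask=mask, level=level)


def niche_area(grid: EnvGrid, region: NicheRegion) -> float:
    """Area of the niche region in squared axis units."""
    return float(region.mask.sum()) * grid.cell_area
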