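"""Voxel-wise binary degree centrality.

For every voxel i in the gray-matter mask, the degree D_i counts the
other mask voxels j whose Pearson correlation with i exceeds a fixed
threshold (default r > 0.25), restricted to positive correlations.
Degree maps are z-standardized within the mask and optionally smoothed.
The pairwise computation runs in voxel blocks, so the full N x N
correlation matrix is never materialized at whole-brain scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bold import BoldSeries
from .masks import GrayMatterMask
from .preprocess import gaussian_smooth

__all__ = ["DegreeMap", "compute_degree_map", "standardize_map", "dc_threshold_sweep"]

logger = logging.getLogger(__name__)


@dataclass
class DegreeMap:
    """Per-mask-voxel degree counts with their standardized (z) map."""

    degree: np.ndarray
    z_value: np.ndarray
    r_threshold: float
    mask: GrayMatterMask

    def __post_init__(self) -> None:
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (-1, 1)")


def _unit_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centre and L2-normalize each voxel's series (columns of data).

    Returns (unit, degenerate) where degenerate flags zero-variance
    voxels; their columns are set to zero so they correlate with nothing.
    """
    x = data - data.mean(axis=0)
    norms = np.linalg.norm(x, axis=0)
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return x / norms, degenerate


def _degree_counts(
    unit: np.ndarray,
    degenerate: np.ndarray,
    thresholds: np.ndarray,
    block_size: int,
) -> np.ndarray:
    """Degree counts per voxel for each threshold; one block of the
    correlation matrix in memory at a time."""
    V = unit.shape[1]
    counts = np.zeros((len(thresholds), V), dtype=np.int64)
    for start in range(0, V, block_size):
        stop = min(start + block_size, V)
        corr = unit[:, start:stop].T @ unit  # (block, V)
        for t, thr in enumerate(thresholds):
            counts[t, start:stop] = (corr > thr).sum(axis=1)
    # remove self-correlation (r = 1) counted for non-degenerate voxels
    for t, thr in enumerate(thresholds):
        if thr < 1.0:
            counts[t, ~degenerate] -= 1
    counts[:, degenerate] = 0
    return counts


def compute_degree_map(
    series: BoldSeries,
    mask: GrayMatterMask | None = None,
    r_threshold: float = 0.25,
    block_size: int = 2048,
    fwhm_mm: float = 0.0,
) -> DegreeMap:
    """Binary degree-centrality map at a positive-correlation threshold.

    Counts strictly r > r_threshold; negative correlations never count.
    Zero-variance voxels get degree 0 (with a logged count) and do not
    contribute to other voxels' degrees.  The z map is the mask-wise
    standardized degree, smoothed with `fwhm_mm` if non-zero.
    """
    mask = mask or series.mask
    if mask.n_voxels < 2:
        raise ValueError("degree centrality needs at least 2 mask voxels")
    unit, degenerate = _unit_rows(series.data)
    n_bad = int(degenerate.sum())
    if n_bad:
        logger.warning("%d zero-variance voxels inside the mask (degree set to 0)", n_bad)
    counts = _degree_counts(unit, degenerate, np.array([r_threshold]), block_size)[0]
    if counts.std() > 0:
        z = standardize_map(counts.astype(float), mask)
    else:  # constant degree map (e.g. tiny saturated masks): z defined as 0
        logger.warning("constant degree map; z map set to zeros")
        z = np.zeros(mask.n_voxels)
    if fwhm_mm:
        z = gaussian_smooth(z, fwhm_mm, mask=mask)
    return DegreeMap(counts, z, r_threshold, mask)


def standardize_map(values: np.ndarray, mask: GrayMatterMask) -> np.ndarray:
    """Mask-wise z-standardization: (x - mean) / SD with population SD.

    Input and output are flat per-mask-voxel arrays; when embedded into
    the grid, values outside the mask are zero by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != mask.n_voxels:
        raise ValueError("value vector does not match mask voxel count")
    if mask.n_voxels < 2:
        raise ValueError("standardization needs at least 2 mask voxels")
    sd = values.std(ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant map (zero SD)")
    return (values - values.mean()) / sd


def dc_threshold_sweep(
    series: BoldSeries,
    mask: GrayMatterMask | None = None,
    thresholds: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    block_size: int = 2048,
) -> list[DegreeMap]:
    """Degree maps over a grid of correlation thresholds (sensitivity sweep)."""
    mask = mask or series.mask
    thr = np.asarray(thresholds, dtype=float)
    if thr.size == 0 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    if np.any(thr < 0) or np.any(thr >= 1):
        raise ValueError("thresholds must lie in [0, 1)")
    unit, degenerate = _unit_rows(series.data)
    counts = _degree_counts(unit, degenerate, thr, block_size)
    maps = []
    for t, r in enumerate(thr):
        c = counts[t].astype(float)
        z = standardize_map(c, mask) if c.std() > 0 else np.zeros_like(c)
        maps.append(DegreeMap(counts[t], z, float(r), mask))
    return maps
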