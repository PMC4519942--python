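"""Seed-based functional connectivity and network reconstruction.

A seed's time series is the unweighted mean over its voxels; the FC map
is the voxel-wise Pearson correlation with that series, Fisher
z-transformed (atanh with the correlation clipped to +/-(1 - 1e-7)).
The group-level network linked to a seed is the set of voxels surviving
a covariate-adjusted one-sample t test on the z maps at the voxel p
threshold with a Monte-Carlo-derived cluster extent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .bold import BoldSeries
from .clusters import label_clusters
from .glm import StatMap, one_sample_t
from .masks import GrayMatterMask

__all__ = ["SeedRegion", "FCMap", "extract_seed_timeseries", "seed_fc_map", "group_network_map"]

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-7


@dataclass
class SeedRegion:
    """Labelled set of mask-voxel indices used as a connectivity seed."""

    label: str
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise ValueError(f"seed '{self.label}' is empty")


@dataclass
class FCMap:
    """Correlation (r) and Fisher-z connectivity map for one subject/seed."""

    r_value: np.ndarray
    z_value: np.ndarray
    seed_label: str = ""


def extract_seed_timeseries(series: BoldSeries, seed: SeedRegion) -> np.ndarray:
    """Unweighted mean time series over the seed voxels."""
    if seed.voxels.min() < 0 or seed.voxels.max() >= series.data.shape[1]:
        raise ValueError(f"seed '{seed.label}' lies outside the mask")
    return series.data[:, seed.voxels].mean(axis=1)


def seed_fc_map(
    series: BoldSeries, seed_ts: np.ndarray, mask: GrayMatterMask | None = None
) -> FCMap:
    """Pearson correlation of every mask voxel with the seed series.

    Constant voxel series get r = 0 (logged); z = atanh of the clipped r.
    """
    seed_ts = np.asarray(seed_ts, dtype=float)
    s = seed_ts - seed_ts.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise ValueError("seed time series is constant")
    x = series.data - series.data.mean(axis=0)
    norms = np.linalg.norm(x, axis=0)
    degenerate = norms == 0
    if degenerate.any():
        logger.warning("%d constant voxels in FC map set to r=0", int(degenerate.sum()))
    norms[degenerate] = 1.0
    r = (x.T @ s) / (norms * s_norm)
    r[degenerate] = 0.0
    r = np.clip(r, -1.0, 1.0)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return FCMap(r, z)


def group_network_map(
    fc_maps: list[FCMap] | np.ndarray,
    covariates: np.ndarray | None,
    mask: GrayMatterMask,
    voxel_p: float,
    extent_k: int,
    connectivity: int = 18,
) -> tuple[StatMap, np.ndarray]:
    """Group one-sample t on Fisher-z maps; surviving voxels form the network.

    Returns the t map and a boolean per-mask-voxel network membership
    vector (clusters of >= extent_k voxels with p < voxel_p).
    """
    Z = np.vstack(
        [m.z_value for m in fc_maps]
        if fc_maps and isinstance(fc_maps[0], FCMap)
        else fc_maps
    )
    n_cov = 0 if covariates is None else np.atleast_2d(np.asarray(covariates)).shape[-1]
    if Z.shape[0] < n_cov + 2:
        raise ValueError("too few subjects for the covariate model")
    tmap = one_sample_t(Z, covariates=covariates, mask=mask)
    records = label_clusters(tmap, voxel_p, extent_k, connectivity=connectivity, mask=mask)
    network = np.zeros(mask.n_voxels, dtype=bool)
    for rec in records:
        network[rec.members] = True
    return tmap, network
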