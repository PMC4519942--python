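"""Analysis masks on a fixed voxel grid.

The analysis domain is a binary gray-matter mask on a 3-D grid with an
affine mapping voxel indices to scanner-space millimetre coordinates.
Synthetic masks are ellipsoids on a centred, isotropic grid; real masks
can be loaded from NIfTI (see :mod:`restmap.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["GrayMatterMask", "generate_mask", "default_tissue_masks"]


def centered_affine(grid_dims: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Diagonal affine with isotropic voxel scaling and the origin at the grid centre."""
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.asarray(grid_dims, dtype=float) - 1) / 2 * voxel_size_mm
    return affine


@dataclass
class GrayMatterMask:
    """Binary 3-D analysis mask with voxel->mm affine.

    Voxel values inside the mask are stored throughout the package as flat
    1-D arrays ordered by ``np.flatnonzero(in_mask)`` (C order).
    """

    in_mask: np.ndarray
    voxel_size_mm: float = 3.0
    affine: np.ndarray | None = None
    _indices: tuple[np.ndarray, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        if self.in_mask.ndim != 3:
            raise ValueError("mask must be a 3-D boolean volume")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not self.in_mask.any():
            raise ValueError("mask contains no voxels")
        if self.affine is None:
            self.affine = centered_affine(self.in_mask.shape, self.voxel_size_mm)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        self._indices = np.nonzero(self.in_mask)

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.in_mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.in_mask.sum())

    @property
    def indices(self) -> tuple[np.ndarray, ...]:
        """Grid indices of mask voxels, in the canonical flat order."""
        return self._indices

    def embed(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-mask-voxel values into a full 3-D grid."""
        values = np.asarray(values)
        if values.shape[-1] != self.n_voxels:
            raise ValueError(
                f"expected {self.n_voxels} mask values, got {values.shape[-1]}"
            )
        out = np.full(self.in_mask.shape, fill, dtype=float)
        out[self._indices] = values
        return out

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Gather mask-voxel values from a full 3-D grid."""
        if volume.shape != self.in_mask.shape:
            raise ValueError("volume shape does not match mask grid")
        return np.asarray(volume)[self._indices]

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates through the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return mm.squeeze()


def generate_mask(
    grid_dims: tuple[int, int, int],
    ellipsoid_radii_mm: tuple[float, float, float],
    voxel_size_mm: float = 3.0,
) -> GrayMatterMask:
    """Ellipsoidal gray-matter stand-in mask on a centred isotropic grid.

    A voxel belongs to the mask when its centre falls strictly inside the
    ellipsoid with the given semi-axes (mm), centred on the grid.  Radii
    exceeding the grid simply saturate the mask at the full grid.
    """
    radii = np.asarray(ellipsoid_radii_mm, dtype=float)
    if radii.shape != (3,) or np.any(radii <= 0):
        raise ValueError("ellipsoid radii must be three positive lengths (mm)")
    if len(grid_dims) != 3 or any(d <= 0 for d in grid_dims):
        raise ValueError("grid_dims must be three positive integers")
    affine = centered_affine(tuple(grid_dims), voxel_size_mm)
    grids = np.indices(grid_dims, dtype=float)
    # centre coordinates in mm along each axis
    normalized = [
        (grids[a] * voxel_size_mm + affine[a, 3]) / radii[a] for a in range(3)
    ]
    in_mask = normalized[0] ** 2 + normalized[1] ** 2 + normalized[2] ** 2 < 1.0
    return GrayMatterMask(in_mask, voxel_size_mm=voxel_size_mm, affine=affine)


def default_tissue_masks(mask: GrayMatterMask) -> tuple[np.ndarray, np.ndarray]:
    """Designate synthetic white-matter and CSF analogue regions.

    Real pipelines extract WM/CSF nuisance means from T1 segmentations;
    on synthetic grids we designate the deepest interior of the mask as a
    CSF analogue and the next depth band as a WM analogue, using the
    Euclidean distance to the mask border.  Returns two boolean grids.
    """
    depth = ndimage.distance_transform_edt(mask.in_mask)
    d = depth[mask.in_mask]
    csf_cut = np.quantile(d, 0.95)
    wm_cut = np.quantile(d, 0.75)
    csf = mask.in_mask & (depth >= csf_cut)
    wm = mask.in_mask & (depth >= wm_cut) & (depth < csf_cut)
    if not csf.any() or not wm.any():  # degenerate tiny masks: fall back to split
        flat = np.flatnonzero(mask.in_mask)
        csf = np.zeros_like(mask.in_mask)
        wm = np.zeros_like(mask.in_mask)
        csf.ravel()[flat[: max(1, len(flat) // 10)]] = True
        wm.ravel()[flat[len(flat) // 10 : max(2, len(flat) // 4)]] = True
    return wm, csf
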