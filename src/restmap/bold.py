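"""In-memory containers for BOLD time series and head-motion traces."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .masks import GrayMatterMask

__all__ = ["BoldSeries", "MotionTrace"]


@dataclass
class BoldSeries:
    """One subject's BOLD run, stored as (n_volumes, n_mask_voxels).

    Values outside the gray-matter mask are never carried; the mask fixes
    the voxel ordering (see :class:`restmap.masks.GrayMatterMask`).
    """

    data: np.ndarray
    tr_seconds: float
    mask: GrayMatterMask
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_volumes, n_mask_voxels)")
        if self.data.shape[1] != self.mask.n_voxels:
            raise ValueError(
                f"series has {self.data.shape[1]} voxels, mask has {self.mask.n_voxels}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("BOLD series contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        return replace(self, data=data)


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (deg)."""

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, float))
        if self.translations_mm.shape != self.rotations_deg.shape:
            raise ValueError("translations and rotations must have the same shape")
        if self.translations_mm.shape[1] != 3:
            raise ValueError("motion trace needs 3 translation and 3 rotation columns")

    @property
    def n_volumes(self) -> int:
        return self.translations_mm.shape[0]

    def max_abs(self) -> tuple[float, float]:
        """Largest per-axis |translation| (mm) and |rotation| (deg) over the run."""
        return (
            float(np.abs(self.translations_mm).max()),
            float(np.abs(self.rotations_deg).max()),
        )

    def as_matrix(self) -> np.ndarray:
        return np.hstack([self.translations_mm, self.rotations_deg])
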