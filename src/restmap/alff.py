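"""Amplitude of low-frequency fluctuations (ALFF).

Per voxel, the time series is Fourier-transformed, the power spectrum
square-rooted, and the resulting amplitudes averaged over the DFT bins
whose frequency lies in the low-frequency band (0.01-0.08 Hz by
default).  Maps are normalized by the global (mask) mean and smoothed.

Conventions: unnormalized DFT of the full series length (no zero
padding); a bin at frequency k/(n*TR) Hz is included when it falls in
the closed band interval.  Under this convention total spectral power
equals n times the time-domain sum of squares (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bold import BoldSeries
from .masks import GrayMatterMask
from .preprocess import BandSpec, gaussian_smooth

__all__ = ["ALFFMap", "compute_alff_map", "normalize_alff"]


@dataclass
class ALFFMap:
    """Raw and (after normalization) global-mean-scaled ALFF per mask voxel."""

    alff_raw: np.ndarray
    band: BandSpec
    mask: GrayMatterMask
    alff_norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alff_raw = np.asarray(self.alff_raw, dtype=float)
        if np.any(self.alff_raw < 0):
            raise ValueError("alff_raw must be non-negative")


def compute_alff_map(
    series: BoldSeries,
    mask: GrayMatterMask | None = None,
    band: BandSpec | None = None,
    tr_seconds: float | None = None,
) -> ALFFMap:
    """Mean square-rooted spectral power over the pass band, per voxel."""
    mask = mask or series.mask
    band = band or BandSpec()
    tr = series.tr_seconds if tr_seconds is None else tr_seconds
    n = series.n_volumes
    freqs = np.fft.rfftfreq(n, d=tr)
    in_band = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not in_band.any():
        raise ValueError(
            f"band ({band.low_hz}, {band.high_hz}) Hz contains no DFT bins "
            f"for n={n}, TR={tr}s"
        )
    amplitude = np.abs(np.fft.rfft(series.data, axis=0))  # sqrt of power
    alff_raw = amplitude[in_band].mean(axis=0)
    return ALFFMap(alff_raw, band, mask)


def normalize_alff(
    alff_map: ALFFMap,
    mask: GrayMatterMask | None = None,
    fwhm_mm: float = 0.0,
) -> ALFFMap:
    """Divide by the global mean over the mask; optionally smooth the result.

    The returned normalized map has mask mean 1 before smoothing.
    """
    mask = mask or alff_map.mask
    global_mean = alff_map.alff_raw.mean()
    if global_mean <= 0:
        raise ValueError("global mean ALFF is zero; cannot normalize")
    norm = alff_map.alff_raw / global_mean
    if fwhm_mm:
        norm = gaussian_smooth(norm, fwhm_mm, mask=mask)
    return replace(alff_map, alff_norm=norm)
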