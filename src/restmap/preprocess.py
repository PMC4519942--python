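"""Temporal preprocessing of BOLD runs and motion screening.

The stage order is fixed and mirrors the conventional resting-state
pipeline: discard equilibration volumes, regress nuisance signals,
remove linear trends, band-pass filter to the low-frequency band.
Spatial Gaussian smoothing (applied later to derived maps) and the
head-motion exclusion filter also live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .bold import BoldSeries, MotionTrace
from .masks import GrayMatterMask

__all__ = [
    "BandSpec",
    "NuisanceSet",
    "build_nuisance_set",
    "discard_initial",
    "regress_nuisance",
    "linear_detrend",
    "bandpass_ideal",
    "summarize_motion",
    "apply_motion_exclusion",
    "gaussian_smooth",
    "fwhm_to_sigma",
    "run_preprocessing",
]

logger = logging.getLogger(__name__)

#: conversion between Gaussian FWHM and standard deviation: 2*sqrt(2*ln 2)
FWHM_SIGMA_RATIO = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma (mm) for a given full width at half maximum (mm)."""
    return fwhm_mm / FWHM_SIGMA_RATIO


@dataclass
class BandSpec:
    """Pass band in Hz; valid when 0 < low < high < Nyquist for the TR in use."""

    low_hz: float = 0.01
    high_hz: float = 0.08

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0.0 < self.low_hz < self.high_hz < nyquist):
            raise ValueError(
                f"band ({self.low_hz}, {self.high_hz}) Hz invalid for "
                f"TR={tr_seconds}s (Nyquist {nyquist:.4f} Hz)"
            )


@dataclass
class NuisanceSet:
    """Named per-volume nuisance regressors (columns of `matrix`)."""

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")
        zero = ~np.any(self.matrix != 0, axis=0)
        if zero.any():
            bad = [n for n, z in zip(self.names, zero) if z]
            raise ValueError(f"constant-zero nuisance column(s): {bad}")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]


def build_nuisance_set(
    series: BoldSeries,
    mask: GrayMatterMask,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    motion: MotionTrace,
) -> NuisanceSet:
    """Global / white-matter / CSF mean signals plus the 6 motion parameters.

    Tissue means are taken over the supplied boolean grids (clipped to the
    analysis mask); signals are extracted from the series as given, i.e.
    after any volume discard already applied to it.
    """
    if motion.n_volumes != series.n_volumes:
        raise ValueError("motion trace length must match series length")
    wm_idx = mask.extract(np.asarray(wm_mask, bool)).astype(bool)
    csf_idx = mask.extract(np.asarray(csf_mask, bool)).astype(bool)
    if not wm_idx.any() or not csf_idx.any():
        raise ValueError("tissue masks must contain at least one mask voxel")
    cols = [
        series.data.mean(axis=1),
        series.data[:, wm_idx].mean(axis=1),
        series.data[:, csf_idx].mean(axis=1),
    ]
    names = ["global", "white_matter", "csf"]
    mot = motion.as_matrix()
    for j, n in enumerate(["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]):
        cols.append(mot[:, j])
        names.append(n)
    return NuisanceSet(np.column_stack(cols), names)


def discard_initial(series: BoldSeries, n_discard: int) -> BoldSeries:
    """Drop the first `n_discard` volumes (signal equilibration)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    return series.with_data(series.data[n_discard:])


def regress_nuisance(series: BoldSeries, nuisance: NuisanceSet) -> BoldSeries:
    """Voxel-wise least-squares removal of the nuisance regressors.

    An intercept is always included so residuals are mean-free.  A
    rank-deficient design is pruned column by column with a warning.
    """
    if nuisance.n_volumes != series.n_volumes:
        raise ValueError("nuisance regressor length must match series length")
    n = series.n_volumes
    X = np.column_stack([np.ones(n), nuisance.matrix])
    names = ["intercept"] + list(nuisance.names)
    # prune collinear columns (keep earliest)
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            msg = f"pruning collinear nuisance regressor '{names[j]}'"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
    X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, series.data, rcond=None)
    return series.with_data(series.data - X @ beta)


def linear_detrend(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel best-fit line (intercept + slope)."""
    n = series.n_volumes
    if n < 3:
        raise ValueError("linear detrend needs at least 3 volumes")
    t = np.arange(n, dtype=float)
    X = np.column_stack([np.ones(n), t - t.mean()])
    beta, *_ = np.linalg.lstsq(X, series.data, rcond=None)
    return series.with_data(series.data - X @ beta)


def _ideal_bandpass(data: np.ndarray, band: BandSpec, tr_seconds: float) -> np.ndarray:
    n = data.shape[0]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    spec = np.fft.rfft(data, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def bandpass_ideal(
    series: BoldSeries, band: BandSpec, tr_seconds: float | None = None
) -> BoldSeries:
    """Ideal (rectangular frequency-domain) band-pass filter.

    DFT coefficients whose frequency lies in the closed interval
    [low, high] are retained, all others (including DC) are zeroed.  The
    rectangular response makes the filter exactly idempotent.
    """
    tr = series.tr_seconds if tr_seconds is None else tr_seconds
    band.validate(tr)
    return series.with_data(_ideal_bandpass(series.data, band, tr))


def summarize_motion(trace: MotionTrace) -> tuple[float, float]:
    """Mean over volumes of the Euclidean norms of translation and rotation."""
    if trace.n_volumes == 0:
        raise ValueError("empty motion trace")
    return (
        float(np.linalg.norm(trace.translations_mm, axis=1).mean()),
        float(np.linalg.norm(trace.rotations_deg, axis=1).mean()),
    )


def apply_motion_exclusion(
    cohort: pd.DataFrame,
    traces: dict[str, MotionTrace],
    limit_mm: float = 1.5,
    limit_deg: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the cohort into kept/excluded by the per-axis motion limits.

    A subject is excluded iff any volume's |translation| on any axis
    exceeds `limit_mm` or any |rotation| exceeds `limit_deg` (strict).
    """
    missing = [s for s in cohort["subject_id"] if s not in traces]
    if missing:
        raise KeyError(f"missing motion trace for subject(s): {missing[:5]}")
    excluded_flags = []
    for sid in cohort["subject_id"]:
        mt, mr = traces[sid].max_abs()
        excluded_flags.append(mt > limit_mm or mr > limit_deg)
    excluded_flags = np.asarray(excluded_flags, dtype=bool)
    kept = cohort.loc[~excluded_flags].reset_index(drop=True)
    excluded = cohort.loc[excluded_flags].reset_index(drop=True)
    logger.info(
        "motion exclusion: kept %d, excluded %d of %d subjects",
        len(kept), len(excluded), len(cohort),
    )
    return kept, excluded


def motion_report(
    cohort: pd.DataFrame,
    traces: dict[str, MotionTrace],
    limit_mm: float = 1.5,
    limit_deg: float = 1.5,
) -> pd.DataFrame:
    """Per-subject exclusion report (max translation/rotation, kept flag)."""
    rows = []
    for sid in cohort["subject_id"]:
        mt, mr = traces[sid].max_abs()
        rows.append(
            {
                "subject_id": sid,
                "max_translation_mm": mt,
                "max_rotation_deg": mr,
                "status": "excluded" if (mt > limit_mm or mr > limit_deg) else "kept",
            }
        )
    return pd.DataFrame(rows)


def gaussian_smooth(
    values: np.ndarray,
    fwhm_mm: float,
    mask: GrayMatterMask | None = None,
    voxel_size_mm: float | None = None,
) -> np.ndarray:
    """3-D Gaussian smoothing with sigma = FWHM / (2*sqrt(2 ln 2)) per axis.

    With a mask, `values` is a flat per-mask-voxel array: it is embedded
    into the full grid (zeros outside), convolved, and re-masked without
    edge renormalization.  Without a mask, `values` is a full 3-D volume.
    `fwhm_mm = 0` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if mask is not None:
        if fwhm_mm == 0:
            return np.asarray(values, dtype=float).copy()
        vol = mask.embed(values)
        sigma = fwhm_to_sigma(fwhm_mm) / mask.voxel_size_mm
        return mask.extract(ndimage.gaussian_filter(vol, sigma))
    if fwhm_mm == 0:
        return np.asarray(values, dtype=float).copy()
    if voxel_size_mm is None:
        raise ValueError("voxel_size_mm required when no mask is given")
    sigma = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    return ndimage.gaussian_filter(np.asarray(values, dtype=float), sigma)


def run_preprocessing(
    series: BoldSeries,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_discard: int = 5,
    band: BandSpec | None = None,
) -> BoldSeries:
    """Full temporal pipeline: discard -> nuisance regression -> detrend -> band-pass.

    Nuisance signals (tissue means and motion parameters) are extracted
    after the volume discard, so the motion trace is truncated to match.
    """
    band = band or BandSpec()
    out = discard_initial(series, n_discard)
    motion_cut = MotionTrace(
        motion.translations_mm[n_discard:], motion.rotations_deg[n_discard:]
    )
    nuis = build_nuisance_set(out, out.mask, wm_mask, csf_mask, motion_cut)
    out = regress_nuisance(out, nuis)
    out = linear_detrend(out)
    out = bandpass_ideal(out, band)
    logger.info(
        "preprocessed %s: discard=%d, band=(%.3f, %.3f) Hz, %d volumes kept",
        series.subject_id, n_discard, band.low_hz, band.high_hz, out.n_volumes,
    )
    return out
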