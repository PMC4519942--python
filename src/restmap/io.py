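"""File formats: NIfTI-1 volumes, motion text, cohort and result TSVs.

Volumes go through nibabel as .nii or .nii.gz with the mask's affine;
motion traces are 6-column whitespace text (3 translations in mm, 3
rotations in degrees); tables are tab-separated with fixed headers.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import BoldSeries, MotionTrace
from .clusters import ClusterRecord, NullClusterDistribution
from .masks import GrayMatterMask
from .synthetic import COHORT_COLUMNS

__all__ = [
    "save_mask", "load_mask", "save_series", "load_series",
    "save_map", "load_map", "save_motion_trace", "load_motion_trace",
    "save_cohort", "load_cohort", "save_null_distribution",
    "load_null_distribution", "cluster_table", "save_config", "load_config",
]


def save_mask(mask: GrayMatterMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.in_mask.astype(np.uint8), mask.affine)
    img.header.set_zooms((mask.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> GrayMatterMask:
    img = nib.load(str(path))
    voxel_size = float(img.header.get_zooms()[0])
    return GrayMatterMask(
        np.asanyarray(img.dataobj) > 0, voxel_size_mm=voxel_size, affine=img.affine
    )


def save_series(series: BoldSeries, path: str | Path) -> None:
    """4-D NIfTI with zeros outside the mask (x, y, z, t)."""
    mask = series.mask
    vol = np.zeros(mask.grid_dims + (series.n_volumes,), dtype=np.float32)
    vol[mask.indices] = series.data.T.astype(np.float32)
    img = nib.Nifti1Image(vol, mask.affine)
    img.header.set_zooms((mask.voxel_size_mm,) * 3 + (series.tr_seconds,))
    nib.save(img, str(path))


def load_series(
    path: str | Path, mask: GrayMatterMask, subject_id: str = ""
) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume")
    tr = float(img.header.get_zooms()[3]) or 2.0
    return BoldSeries(
        data[mask.indices].T.astype(float), tr_seconds=tr, mask=mask,
        subject_id=subject_id or Path(path).stem.split(".")[0],
    )


def save_map(values: np.ndarray, mask: GrayMatterMask, path: str | Path) -> None:
    """Per-mask-voxel statistic/map embedded into the grid (zeros outside)."""
    img = nib.Nifti1Image(mask.embed(values).astype(np.float32), mask.affine)
    nib.save(img, str(path))


def load_map(path: str | Path, mask: GrayMatterMask) -> np.ndarray:
    img = nib.load(str(path))
    return mask.extract(np.asanyarray(img.dataobj).astype(float))


def save_motion_trace(trace: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), trace.as_matrix(), fmt="%.6f")


def load_motion_trace(path: str | Path) -> MotionTrace:
    m = np.loadtxt(str(path))
    if m.ndim == 1:
        m = m[None, :]
    if m.shape[1] != 6:
        raise ValueError(f"{path}: motion trace must have 6 columns")
    return MotionTrace(m[:, :3], m[:, 3:])


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(str(path), sep="\t", index=False, columns=COHORT_COLUMNS)


def load_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    return df


def save_null_distribution(
    null: NullClusterDistribution, path: str | Path, mask_hash: str = ""
) -> None:
    """TSV of per-iteration maximum cluster sizes, with a parameter header."""
    header = (
        f"# voxel_p: {null.voxel_p}\n# fwhm_mm: {null.fwhm_mm}\n"
        f"# connectivity: {null.connectivity}\n# two_sided: {null.two_sided}\n"
        f"# seed: {null.seed}\n# mask_hash: {mask_hash}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("iteration\tmax_cluster_size\n")
        for i, s in enumerate(null.max_cluster_sizes):
            fh.write(f"{i}\t{int(s)}\n")


def load_null_distribution(path: str | Path) -> NullClusterDistribution:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            body.append(line)
    df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t")
    return NullClusterDistribution(
        df["max_cluster_size"].to_numpy(int),
        voxel_p=float(meta.get("voxel_p", "nan")),
        fwhm_mm=float(meta.get("fwhm_mm", "nan")),
        connectivity=int(meta.get("connectivity", "18")),
        two_sided=meta.get("two_sided", "False") == "True",
    )


def cluster_table(records: list[ClusterRecord]) -> pd.DataFrame:
    """Cluster report mirroring the usual table layout (no atlas labels)."""
    return pd.DataFrame(
        [
            {
                "region": "n/a",
                "voxels": r.voxel_count,
                "peak_stat": round(r.peak_stat, 4),
                "x_mm": round(float(r.peak_mm[0]), 2),
                "y_mm": round(float(r.peak_mm[1]), 2),
                "z_mm": round(float(r.peak_mm[2]), 2),
            }
            for r in records
        ],
        columns=["region", "voxels", "peak_stat", "x_mm", "y_mm", "z_mm"],
    )


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
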