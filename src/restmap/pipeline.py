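"""End-to-end orchestration of the analysis on synthetic cohorts.

Ties the stages together: simulate a cohort, screen motion, preprocess,
map degree centrality and ALFF, run the sex-by-diagnosis ANCOVA with
Monte-Carlo cluster-extent correction, reconstruct seed networks, and
correlate ROI values with clinical scores.  Every artifact (NIfTI maps,
TSV tables, the parameter echo and a run log) lands in the output
directory; all stochastic stages draw from explicit seeds in the
configuration, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .alff import compute_alff_map, normalize_alff
from .clinical import correlate_with_scores, correlation_table
from .clusters import extent_threshold, label_clusters, simulate_null_max_clusters
from .cohort_stats import table_one
from .degree import compute_degree_map
from .glm import build_design, f_contrast, fit_glm_voxelwise, posthoc_t_within_mask
from .masks import GrayMatterMask, default_tissue_masks, generate_mask
from .preprocess import BandSpec, apply_motion_exclusion, motion_report, run_preprocessing
from .seedfc import FCMap, SeedRegion, extract_seed_timeseries, group_network_map, seed_fc_map
from .synthetic import (
    AmplitudeRegion, ClinicalCoupling, CohortSpec, Community, EffectSpec, generate_cohort,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "grid_dims": [16, 16, 16],
    "ellipsoid_radii_mm": [21.0, 21.0, 21.0],
    "voxel_size_mm": 3.0,
    "cohort": {
        "n_fes_male": 10, "n_fes_female": 10, "n_hc_male": 10, "n_hc_female": 10,
        "violators_fes": 2, "violators_hc": 1,
        "treated_male": 2, "treated_female": 2,
        "n_volumes": 120, "tr_seconds": 2.0,
    },
    "n_discard": 5,
    "band": [0.01, 0.08],
    "r_threshold": 0.25,
    "fwhm_mm": 6.0,
    "voxel_p": 0.001,
    "alpha": 0.05,
    "n_iterations": 1000,
    "connectivity": 18,
    "save_volumes": False,
    "seeds": {"simulate": None, "null": None},
}


def validate_config(config: dict) -> dict:
    """Merge with defaults and insist on explicit seeds for stochastic stages."""
    merged = {**DEFAULT_CONFIG, **(config or {})}
    merged["cohort"] = {**DEFAULT_CONFIG["cohort"], **(config or {}).get("cohort", {})}
    merged["seeds"] = {**DEFAULT_CONFIG["seeds"], **(config or {}).get("seeds", {})}
    for stage, seed in merged["seeds"].items():
        if seed is None:
            raise ValueError(f"config error: stochastic stage '{stage}' has no seed")
    return merged


def demo_effects(mask: GrayMatterMask, config: dict) -> EffectSpec:
    """Ground-truth effects for demonstration runs.

    The whole mask is partitioned into octant communities (so degree
    maps are link-driven, as in real resting-state data); one octant is
    the connectivity hub whose coupling collapses in male patients only
    (the selective-degree-reduction scenario), another octant's local
    fluctuation amplitude is raised in patients, with a clinical
    coupling tying that region's amplitude to the disorganized/concrete
    score.
    """
    from .masks import default_tissue_masks
    from .synthetic import octant_partition

    wm, csf = default_tissue_masks(mask)
    tissue = mask.extract(wm | csf).astype(bool)
    parts = octant_partition(mask, exclude=tissue)
    labels = sorted(k for k in parts if k.startswith("octant"))
    hub_label, amp_label = labels[-1], labels[0]
    communities = []
    for label, vox in parts.items():
        if label == hub_label:
            communities.append(
                Community(
                    "hub", vox,
                    coupling={"FESm": 0.2, "FESf": 1.0, "HCm": 1.0, "HCf": 1.0},
                )
            )
        else:
            communities.append(Community(label, vox, 1.0))
    return EffectSpec(
        communities=communities,
        amplitude_regions=[
            AmplitudeRegion(
                "amp", parts[amp_label],
                multiplier={"FESm": 1.5, "FESf": 1.5, "HCm": 1.0, "HCf": 1.0},
            )
        ],
        background_amplitude=1.0,
        noise_sd=1.0,
        clinical_couplings=[ClinicalCoupling("amp", "panss_dc", 0.4)],
        band=BandSpec(*config["band"]),
    )


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the full analysis; returns a summary of key outputs."""
    config = validate_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("restmap")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {}
    try:
        io.save_config(config, out / "config.yaml")

        # --- simulate -------------------------------------------------
        logger.info("stage simulate: generating mask and cohort")
        mask = generate_mask(
            tuple(config["grid_dims"]),
            tuple(config["ellipsoid_radii_mm"]),
            config["voxel_size_mm"],
        )
        io.save_mask(mask, out / "mask.nii.gz")
        effects = demo_effects(mask, config)
        cohort_spec = CohortSpec(**config["cohort"])
        series, traces, cohort = generate_cohort(
            cohort_spec, effects, mask, config["seeds"]["simulate"]
        )
        io.save_cohort(cohort, out / "cohort.tsv")
        by_id = {s.subject_id: s for s in series}
        if config["save_volumes"]:
            vol_dir = out / "bold"
            vol_dir.mkdir(exist_ok=True)
            for s in series:
                io.save_series(s, vol_dir / f"{s.subject_id}_bold.nii.gz")
            for sid, tr in traces.items():
                io.save_motion_trace(tr, vol_dir / f"{sid}_motion.txt")

        # --- motion exclusion -----------------------------------------
        kept, excluded = apply_motion_exclusion(cohort, traces)
        motion_report(cohort, traces).to_csv(
            out / "motion_exclusion.tsv", sep="\t", index=False
        )
        summary["n_kept"] = len(kept)
        summary["n_excluded"] = len(excluded)
        logger.info("stage exclusion: kept %d excluded %d", len(kept), len(excluded))

        # --- preprocess + subject-level maps --------------------------
        band = BandSpec(*config["band"])
        wm, csf = default_tissue_masks(mask)
        fwhm = config["fwhm_mm"]
        dc_maps, alff_maps = [], []
        for sid in kept["subject_id"]:
            pre = run_preprocessing(
                by_id[sid], traces[sid], wm, csf,
                n_discard=config["n_discard"], band=band,
            )
            dm = compute_degree_map(
                pre, mask, r_threshold=config["r_threshold"], fwhm_mm=fwhm
            )
            dc_maps.append(dm.z_value)
            am = normalize_alff(compute_alff_map(pre, mask, band), mask, fwhm_mm=fwhm)
            alff_maps.append(am.alff_norm)
        dc_maps = np.vstack(dc_maps)
        alff_maps = np.vstack(alff_maps)
        logger.info("stage maps: %d DC and ALFF maps computed", dc_maps.shape[0])

        # --- cohort table statistics ----------------------------------
        table_one(kept).to_csv(out / "table_one.tsv", sep="\t", index=False)

        # --- cluster-extent null --------------------------------------
        null = simulate_null_max_clusters(
            mask, fwhm, config["voxel_p"], config["n_iterations"],
            connectivity=config["connectivity"], seed=config["seeds"]["null"],
        )
        io.save_null_distribution(null, out / "null_max_clusters.tsv")
        k = extent_threshold(null, config["alpha"])
        summary["extent_threshold_voxels"] = k
        logger.info("stage cluster-null: extent threshold k=%d voxels", k)

        # --- group statistics -----------------------------------------
        X, names = build_design(kept, covariates=("age",))
        subgroup = kept["subgroup"].to_numpy()
        age = kept["age"].to_numpy(float)
        for label, maps in (("dc", dc_maps), ("alff", alff_maps)):
            fit = fit_glm_voxelwise(maps, X, names)
            tables = []
            for term in ("interaction", "sex", "diagnosis"):
                fmap = f_contrast(fit, term, mask)
                io.save_map(fmap.stat_value, mask, out / f"{label}_F_{term}.nii.gz")
                io.save_map(fmap.p_value, mask, out / f"{label}_p_{term}.nii.gz")
                recs = label_clusters(
                    fmap, config["voxel_p"], k, config["connectivity"], mask
                )
                tab = io.cluster_table(recs)
                tab.insert(0, "contrast", term)
                tables.append(tab)
                if term == "interaction" and recs:
                    sup = np.zeros(mask.n_voxels, dtype=bool)
                    for r in recs:
                        sup[r.members] = True
                    for sex_label, sex_name in (("m", "male"), ("f", "female")):
                        selA = (subgroup == f"HC{sex_label}")
                        selB = (subgroup == f"FES{sex_label}")
                        tmap = posthoc_t_within_mask(
                            maps[selA], maps[selB], sup,
                            covariates=(age[selA], age[selB]), mask=mask,
                        )
                        io.save_map(
                            np.nan_to_num(tmap.stat_value), mask,
                            out / f"{label}_posthoc_HC_gt_FES_{sex_name}.nii.gz",
                        )
            filled = [t for t in tables if not t.empty]
            header = tables[0].columns if not filled else filled[0].columns
            combined = (
                pd.concat(filled, ignore_index=True)
                if filled else pd.DataFrame(columns=header)
            )
            combined.to_csv(out / f"{label}_clusters.tsv", sep="\t", index=False)
        logger.info("stage group-stats: contrasts and post-hoc maps written")

        # --- seed network (healthy controls) --------------------------
        fit = fit_glm_voxelwise(dc_maps, X, names)
        fmap = f_contrast(fit, "interaction", mask)
        recs = label_clusters(fmap, config["voxel_p"], k, config["connectivity"], mask)
        seed_voxels = recs[0].members if recs else effects.communities[0].voxels
        seed = SeedRegion("interaction_peak", seed_voxels)
        hc = kept["diagnosis"].to_numpy() == "HC"
        hc_ids = kept.loc[hc, "subject_id"]
        fc_maps: list[FCMap] = []
        for sid in hc_ids:
            pre = run_preprocessing(
                by_id[sid], traces[sid], wm, csf,
                n_discard=config["n_discard"], band=band,
            )
            fc_maps.append(seed_fc_map(pre, extract_seed_timeseries(pre, seed), mask))
        tmap, network = group_network_map(
            fc_maps, kept.loc[hc, "age"].to_numpy(float)[:, None], mask,
            config["voxel_p"], k, config["connectivity"],
        )
        io.save_map(tmap.stat_value, mask, out / "seed_network_t.nii.gz")
        io.save_map(network.astype(float), mask, out / "seed_network_mask.nii.gz")
        summary["network_voxels"] = int(network.sum())
        logger.info("stage seed-fc: network of %d voxels", int(network.sum()))

        # --- clinical correlations ------------------------------------
        patients = kept["diagnosis"].to_numpy() == "FES"
        pat = kept.loc[patients]
        pat_alff = alff_maps[patients]
        rois = {
            "hub": effects.communities[0].voxels,
            "amp": effects.amplitude_regions[0].voxels,
        }
        roi_values = {
            name: pat_alff[:, vox].mean(axis=1) for name, vox in rois.items()
        }
        scores = {
            s: pat[s].to_numpy(float)
            for s in ("panss_total", "panss_dc", "panss_depressed")
        }
        strata = {
            "male": (pat["sex"] == "male").to_numpy(),
            "female": (pat["sex"] == "female").to_numpy(),
            "combined": np.ones(len(pat), dtype=bool),
        }
        results = correlate_with_scores(
            roi_values, scores, strata, family_alpha=0.05, n_tests=8
        )
        correlation_table(results).to_csv(
            out / "clinical_correlations.tsv", sep="\t", index=False
        )
        logger.info("stage correlate: %d correlation rows", len(results))
        summary["outdir"] = str(out)
        return summary
    except Exception as exc:  # stage-labelled failure, partial outputs retained
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
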