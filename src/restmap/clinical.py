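"""ROI-clinical correlations under Bonferroni control.

Mean DC/ALFF values over regions of interest are correlated (Pearson,
optionally Spearman) with PANSS scores, per stratum (male patients,
female patients, combined).  The per-test threshold is the family alpha
divided by the number of ROIs (8 in the reference design, giving
0.05/8 = 0.00625, displayed as 0.006).  Results carry a reporting tier:
"significant" below the Bonferroni threshold, "suggestive" below the
uncorrected 0.05, otherwise "ns".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "roi_mean",
    "correlate_with_scores",
    "bonferroni_alpha",
    "correlation_table",
]


@dataclass
class CorrelationResult:
    roi: str
    score: str
    stratum: str
    r: float
    p: float
    n: int
    significant: bool
    tier: str


def roi_mean(values: np.ndarray, roi_voxels: np.ndarray) -> float:
    """Unweighted mean of a per-mask-voxel map over the ROI voxels."""
    values = np.asarray(values, dtype=float)
    roi = np.asarray(roi_voxels, dtype=int)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if roi.min() < 0 or roi.max() >= values.shape[-1]:
        raise ValueError("ROI indices outside the map")
    return float(values[roi].mean())


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha: family alpha divided by the number of tests."""
    if m < 1:
        raise ValueError("number of tests must be at least 1")
    return family_alpha / m


def correlate_with_scores(
    roi_values: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    groups: dict[str, np.ndarray],
    family_alpha: float = 0.05,
    n_tests: int | None = None,
    method: str = "pearson",
    suggestive_p: float = 0.05,
) -> list[CorrelationResult]:
    """Correlate each (ROI, score) pair within each group stratum.

    `roi_values` and `scores` map labels to aligned per-subject arrays;
    `groups` maps stratum labels to boolean subject selectors.  Pairs
    with missing values are dropped pairwise; n >= 4 is required.  The
    Bonferroni divisor defaults to the number of ROIs.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    m = n_tests if n_tests is not None else len(roi_values)
    threshold = bonferroni_alpha(family_alpha, m)
    results: list[CorrelationResult] = []
    for stratum, sel in groups.items():
        sel = np.asarray(sel, dtype=bool)
        for roi_label, rv in roi_values.items():
            for score_label, sv in scores.items():
                x = np.asarray(rv, dtype=float)[sel]
                y = np.asarray(sv, dtype=float)[sel]
                ok = np.isfinite(x) & np.isfinite(y)
                x, y = x[ok], y[ok]
                if len(x) < 4:
                    raise ValueError(
                        f"fewer than 4 paired observations for "
                        f"({roi_label}, {score_label}, {stratum})"
                    )
                if x.std() == 0 or y.std() == 0:
                    raise ValueError(
                        f"zero variance in ({roi_label}, {score_label}, {stratum})"
                    )
                if method == "pearson":
                    r, p = stats.pearsonr(x, y)
                else:
                    r, p = stats.spearmanr(x, y)
                sig = bool(p < threshold)
                tier = "significant" if sig else ("suggestive" if p < suggestive_p else "ns")
                results.append(
                    CorrelationResult(
                        roi_label, score_label, stratum,
                        float(r), float(p), int(len(x)), sig, tier,
                    )
                )
    return results


def correlation_table(results: list[CorrelationResult]) -> pd.DataFrame:
    """Result rows as a tidy table (stratum, ROI, score, n, r, p, tier)."""
    return pd.DataFrame(
        [
            {
                "stratum": r.stratum, "roi": r.roi, "score": r.score,
                "n": r.n, "r": r.r, "p": r.p, "tier": r.tier,
            }
            for r in results
        ]
    )
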