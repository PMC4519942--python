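"""Group comparisons of demographic, clinical and head-motion variables.

Demographics and motion summaries are compared across the four
sex-by-diagnosis subgroups with one-way ANOVA; clinical variables,
which exist only for patients, are compared between male and female
patients with a two-sample t test (pooled variance by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SUBGROUPS

__all__ = ["GroupComparison", "compare_groups", "table_one"]

FOUR_GROUP_VARIABLES = (
    "age", "education_years", "mean_translation_mm", "mean_rotation_deg",
)
PATIENT_VARIABLES = (
    "panss_total", "panss_positive", "panss_negative", "panss_dc",
    "panss_excited", "panss_depressed", "dup_months", "onset_age",
)


@dataclass
class GroupComparison:
    variable: str
    test: str  # "anova" (4 subgroups) or "t" (male vs female patients)
    statistic: float
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]


def compare_groups(
    cohort: pd.DataFrame, variable: str, welch: bool = False
) -> GroupComparison:
    """Compare one variable across the appropriate groups.

    Demographic/motion variables -> one-way ANOVA over the four
    subgroups; clinical variables -> male-vs-female patient t test.
    """
    if variable in FOUR_GROUP_VARIABLES:
        samples = []
        means, sds = {}, {}
        for sg in SUBGROUPS:
            v = cohort.loc[cohort["subgroup"] == sg, variable].dropna().to_numpy(float)
            if len(v) < 2:
                raise ValueError(f"subgroup {sg} has fewer than 2 observations")
            samples.append(v)
            means[sg], sds[sg] = float(v.mean()), float(v.std(ddof=1))
        if all(s.std(ddof=0) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.f_oneway(*samples)
        return GroupComparison(variable, "anova", float(stat), float(p), means, sds)
    if variable in PATIENT_VARIABLES:
        means, sds = {}, {}
        groups = []
        for sg in ("FESm", "FESf"):
            v = cohort.loc[cohort["subgroup"] == sg, variable].dropna().to_numpy(float)
            if len(v) < 2:
                raise ValueError(f"subgroup {sg} has fewer than 2 observations")
            groups.append(v)
            means[sg], sds[sg] = float(v.mean()), float(v.std(ddof=1))
        stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=not welch)
        return GroupComparison(variable, "t", float(stat), float(p), means, sds)
    raise ValueError(f"unknown comparison variable '{variable}'")


def table_one(cohort: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Cohort characteristics table: per-group mean (SD) and the test p."""
    rows = []
    for variable in FOUR_GROUP_VARIABLES + PATIENT_VARIABLES:
        try:
            cmp = compare_groups(cohort, variable, welch=welch)
        except ValueError:
            continue
        row = {"variable": variable, "test": cmp.test}
        for sg in SUBGROUPS:
            if sg in cmp.group_means:
                row[sg] = f"{cmp.group_means[sg]:.2f} ({cmp.group_sds[sg]:.2f})"
            else:
                row[sg] = "-"
        row["p"] = round(cmp.p, 4)
        rows.append(row)
    return pd.DataFrame(rows)
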