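"""Synthetic resting-state cohorts with known ground truth.

Emulates a 2x2 first-episode schizophrenia (FES) / healthy control (HC)
by male/female cohort: 4-D BOLD-like runs on a common 3-mm grid
(TR = 2 s, 200 volumes), six-parameter head-motion traces with
controllable limit violators, and a demographic/clinical table whose
marginals follow the published group characteristics (ages ~24-25 y,
PANSS totals ~88, etc.).

Signal model per voxel: a community-shared latent band-limited
(0.01-0.08 Hz) signal scaled by a coupling weight w, an independent
per-voxel band-limited "local fluctuation" scaled by an amplitude
multiplier, and white Gaussian noise.  With unit-variance latents the
expected correlation of two voxels in the same community is
w^2 / (w^2 + a^2 + sigma^2), where a is the local amplitude and sigma
the noise level — which makes hub- and amplitude-recovery testable in
closed form.  Group x sex effects are injected by making coupling
weights or amplitude multipliers subgroup-specific; clinical coupling
ties a subject's region amplitude and a PANSS score to a shared latent
scalar, yielding a tunable expected correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bold import BoldSeries, MotionTrace
from .masks import GrayMatterMask
from .preprocess import BandSpec, summarize_motion

__all__ = [
    "SUBGROUPS",
    "Community",
    "AmplitudeRegion",
    "ClinicalCoupling",
    "EffectSpec",
    "CohortSpec",
    "generate_mask",  # re-export: mask generation is part of the generator surface
    "octant_partition",
    "generate_subject_series",
    "generate_motion_trace",
    "generate_cohort",
]

from .masks import generate_mask  # noqa: E402  (re-export)

SUBGROUPS = ("FESm", "FESf", "HCm", "HCf")

# Published group marginals: mean, SD per subgroup (FESm, FESf, HCm, HCf),
# plus truncation bounds.  Clinical scores exist only for patients; the five
# syndrome scores use the five-factor item ranges, the total its 30-item range.
_DEMOGRAPHICS = {
    "age": ((24.31, 6.57), (24.62, 6.82), (24.80, 6.74), (24.71, 6.98), (16.0, 60.0)),
    "education_years": (
        (13.13, 2.49), (12.94, 2.49), (13.77, 2.91), (13.40, 2.55), (5.0, 22.0)
    ),
}
_CLINICAL = {
    "panss_total": ((87.59, 17.07), (89.27, 17.04), (30.0, 210.0)),
    "panss_positive": ((14.74, 4.40), (15.77, 4.24), (4.0, 28.0)),
    "panss_negative": ((16.58, 7.73), (14.85, 8.39), (6.0, 42.0)),
    "panss_dc": ((9.12, 2.75), (9.48, 2.96), (3.0, 21.0)),
    "panss_excited": ((9.93, 3.85), (11.32, 4.13), (4.0, 28.0)),
    "panss_depressed": ((6.19, 3.08), (6.12, 2.71), (3.0, 21.0)),
    "dup_months": ((8.19, 8.97), (5.50, 8.03), (0.0, 240.0)),
    "onset_age": ((23.24, 6.65), (23.76, 6.64), (13.0, 60.0)),
}

COHORT_COLUMNS = [
    "subject_id", "diagnosis", "sex", "subgroup", "age", "education_years",
    "panss_total", "panss_positive", "panss_negative", "panss_dc",
    "panss_excited", "panss_depressed", "dup_months", "onset_age",
    "treated_flag", "violator", "mean_translation_mm", "mean_rotation_deg",
]


def _resolve(value: float | dict, subgroup: str) -> float:
    if isinstance(value, dict):
        return float(value[subgroup])
    return float(value)


@dataclass
class Community:
    """Voxel set sharing one latent signal with coupling weight w (per subgroup)."""

    label: str
    voxels: np.ndarray
    coupling: float | dict = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        weights = (
            self.coupling.values() if isinstance(self.coupling, dict)
            else [self.coupling]
        )
        if any(w < 0 for w in weights):
            raise ValueError(f"community '{self.label}': coupling weights must be >= 0")


@dataclass
class AmplitudeRegion:
    """Voxel set whose local fluctuation amplitude is scaled by a multiplier."""

    label: str
    voxels: np.ndarray
    multiplier: float | dict = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)


@dataclass
class ClinicalCoupling:
    """Share a latent scalar between a region's amplitude and a PANSS score."""

    roi_label: str
    score: str
    target_r: float
    gain: float = 0.5  # relative amplitude modulation per latent SD

    def __post_init__(self) -> None:
        if not (-1.0 < self.target_r < 1.0):
            raise ValueError("target correlation must lie in (-1, 1)")
        if self.score not in _CLINICAL:
            raise ValueError(f"unknown clinical score '{self.score}'")


@dataclass
class EffectSpec:
    """Ground-truth effect structure injected into generated cohorts."""

    communities: list[Community] = field(default_factory=list)
    amplitude_regions: list[AmplitudeRegion] = field(default_factory=list)
    background_amplitude: float = 0.0
    noise_sd: float = 1.0
    clinical_couplings: list[ClinicalCoupling] = field(default_factory=list)
    band: BandSpec = field(default_factory=BandSpec)

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        labels = {r.label for r in self.amplitude_regions}
        for c in self.clinical_couplings:
            if c.roi_label not in labels:
                raise ValueError(
                    f"clinical coupling references unknown region '{c.roi_label}'"
                )

    def validate_against(self, mask: GrayMatterMask) -> None:
        n = mask.n_voxels
        for group in (self.communities, self.amplitude_regions):
            for r in group:
                if r.voxels.size and (r.voxels.min() < 0 or r.voxels.max() >= n):
                    raise ValueError(f"region '{r.label}' voxels outside mask")


@dataclass
class CohortSpec:
    """Subgroup sizes and bookkeeping for the emulated 2x2 cohort.

    Defaults reproduce the study conditions: 61/63/50/52 included
    subjects per subgroup, 21 patient and 14 control motion violators
    on top (pre-exclusion totals 145 patients / 116 controls), and 28
    minimally treated patients (15 male, 13 female) among the included.
    """

    n_fes_male: int = 61
    n_fes_female: int = 63
    n_hc_male: int = 50
    n_hc_female: int = 52
    violators_fes: int = 21
    violators_hc: int = 14
    treated_male: int = 15
    treated_female: int = 13
    n_volumes: int = 200
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        sizes = [
            self.n_fes_male, self.n_fes_female, self.n_hc_male, self.n_hc_female,
            self.violators_fes, self.violators_hc,
            self.treated_male, self.treated_female,
        ]
        if any(s < 0 for s in sizes):
            raise ValueError("cohort sizes and counts must be non-negative")
        if self.treated_male > self.n_fes_male or self.treated_female > self.n_fes_female:
            raise ValueError("treated counts exceed included patient counts")


def octant_partition(
    mask: GrayMatterMask, exclude: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Partition mask voxels into 8 spatial octants around the grid centre.

    Returns label -> flat mask-voxel indices.  Voxels flagged in
    `exclude` (boolean per mask voxel) are collected under ``"deep"``
    instead; this keeps injected communities clear of the designated
    WM/CSF nuisance regions, whose mean signals are regressed out.
    Realistic resting-state data is covered by correlated networks
    everywhere, so recovery fixtures should partition the whole mask
    rather than embed a single community in independent noise.
    """
    ii, jj, kk = mask.indices
    centre = (np.array(mask.grid_dims) - 1) / 2
    code = (
        (ii > centre[0]).astype(int) * 4
        + (jj > centre[1]).astype(int) * 2
        + (kk > centre[2]).astype(int)
    )
    excl = (
        np.zeros(mask.n_voxels, dtype=bool)
        if exclude is None
        else np.asarray(exclude, dtype=bool)
    )
    out = {
        f"octant{o}": np.flatnonzero((code == o) & ~excl) for o in range(8)
    }
    out = {k: v for k, v in out.items() if v.size}
    if excl.any():
        out["deep"] = np.flatnonzero(excl)
    return out


def band_limited_noise(
    rng: np.random.Generator,
    n_volumes: int,
    tr_seconds: float,
    n_signals: int,
    band: BandSpec,
) -> np.ndarray:
    """Unit-SD Gaussian signals ideally band-limited to the pass band.

    Columns are independent; each is white noise passed through the same
    rectangular DFT filter used in preprocessing, then rescaled to unit
    sample standard deviation.
    """
    x = rng.standard_normal((n_volumes, n_signals))
    freqs = np.fft.rfftfreq(n_volumes, d=tr_seconds)
    keep = (freqs >= band.low_hz) & (freqs <= band.high_hz)
    if not keep.any():
        raise ValueError("band contains no DFT bins at this length/TR")
    spec = np.fft.rfft(x, axis=0)
    spec[~keep] = 0.0
    y = np.fft.irfft(spec, n=n_volumes, axis=0)
    sd = y.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return y / sd


def generate_subject_series(
    mask: GrayMatterMask,
    effect_spec: EffectSpec,
    tr_seconds: float,
    n_volumes: int,
    seed: int | np.random.SeedSequence,
    subgroup: str = "HCm",
    subject_id: str = "",
    amplitude_jitter: dict[str, float] | None = None,
) -> BoldSeries:
    """Generate one subject's BOLD-like run from the effect specification.

    `amplitude_jitter` maps amplitude-region labels to per-subject
    multiplicative factors (used by clinical coupling).  Deterministic
    given the seed; the draw order is fixed (noise, local fluctuations,
    community latents).
    """
    if n_volumes < 10:
        raise ValueError("n_volumes must be at least 10")
    if subgroup not in SUBGROUPS:
        raise ValueError(f"unknown subgroup '{subgroup}'")
    effect_spec.validate_against(mask)
    rng = np.random.default_rng(seed)
    V = mask.n_voxels
    data = effect_spec.noise_sd * rng.standard_normal((n_volumes, V))

    amp = np.full(V, effect_spec.background_amplitude, dtype=float)
    for region in effect_spec.amplitude_regions:
        m = _resolve(region.multiplier, subgroup)
        if amplitude_jitter and region.label in amplitude_jitter:
            m *= amplitude_jitter[region.label]
        base = effect_spec.background_amplitude if effect_spec.background_amplitude else 1.0
        amp[region.voxels] = base * max(m, 0.0)
    if np.any(amp > 0):
        local = band_limited_noise(
            rng, n_volumes, tr_seconds, V, effect_spec.band
        )
        data += amp * local

    for community in effect_spec.communities:
        w = _resolve(community.coupling, subgroup)
        latent = band_limited_noise(rng, n_volumes, tr_seconds, 1, effect_spec.band)
        if w > 0 and community.voxels.size:
            data[:, community.voxels] += w * latent

    return BoldSeries(data, tr_seconds=tr_seconds, mask=mask, subject_id=subject_id)


def generate_motion_trace(
    n_volumes: int,
    violator: bool,
    seed: int | np.random.SeedSequence,
    limit_mm: float = 1.5,
    limit_deg: float = 1.5,
) -> MotionTrace:
    """Slow-drift motion trace; violators exceed the exclusion limits.

    Non-violators stay within |1.0| mm and |1.0| degree on every axis;
    violators get a single spike beyond the stated limit on a random
    axis (translation or rotation, coin flip).
    """
    rng = np.random.default_rng(seed)
    out = []
    # slow drift + jitter, capped well inside the limits; the scale puts the
    # per-volume norm summaries near the published ~0.11-0.13 mm / degree
    for _ in range(2):  # translations then rotations
        walk = np.cumsum(rng.normal(0.0, 0.008, size=(n_volumes, 3)), axis=0)
        walk += rng.normal(0.0, 0.004, size=(n_volumes, 3))
        peak = np.abs(walk).max()
        if peak > 0.4:
            walk *= 0.4 / peak
        out.append(walk)
    trans, rot = out
    if violator:
        vol = int(rng.integers(1, n_volumes))
        axis = int(rng.integers(0, 3))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        excess = float(rng.uniform(0.1, 1.0))
        if rng.random() < 0.5:
            trans[vol, axis] = sign * (limit_mm + excess)
        else:
            rot[vol, axis] = sign * (limit_deg + excess)
    return MotionTrace(trans, rot)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Gaussian draws clipped to the instrument bounds (bounds rarely active)."""
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def _clinical_scores(
    rng: np.random.Generator,
    subgroup: str,
    n: int,
    couplings: list[ClinicalCoupling],
    latents: dict[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Per-patient clinical scores; coupled scores share the region latent."""
    col = 0 if subgroup == "FESm" else 1
    coupled = {c.score: c for c in couplings}
    scores: dict[str, np.ndarray] = {}
    for name, spec in _CLINICAL.items():
        (mean, sd), lo, hi = spec[col], spec[2][0], spec[2][1]
        if name in coupled:
            c = coupled[name]
            u = latents[c.roi_label]
            eps = rng.standard_normal(n)
            z = c.target_r * u + np.sqrt(1.0 - c.target_r**2) * eps
            scores[name] = np.clip(mean + sd * z, lo, hi)
        else:
            scores[name] = _truncated_normal(rng, mean, sd, lo, hi, n)
    return scores


def generate_cohort(
    cohort_spec: CohortSpec,
    effect_spec: EffectSpec,
    mask: GrayMatterMask,
    seed: int | np.random.SeedSequence,
    generate_series: bool = True,
) -> tuple[list[BoldSeries], dict[str, MotionTrace], pd.DataFrame]:
    """Generate the full 2x2 cohort: BOLD runs, motion traces, cohort table.

    Violator subjects are appended on top of the included counts, so the
    table holds the pre-exclusion cohort; running the motion-exclusion
    filter recovers the included subgroup sizes exactly.  With
    `generate_series=False` the BOLD runs are skipped (empty list),
    which keeps table-level work at full cohort size cheap.
    """
    effect_spec.validate_against(mask)
    ss = (
        seed if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    table_rng = np.random.default_rng(ss.spawn(1)[0])

    # roster: (subgroup, violator) per subject; violators alternate sexes
    roster: list[tuple[str, bool]] = []
    for sg, n in zip(
        SUBGROUPS,
        (cohort_spec.n_fes_male, cohort_spec.n_fes_female,
         cohort_spec.n_hc_male, cohort_spec.n_hc_female),
    ):
        roster += [(sg, False)] * n
    for i in range(cohort_spec.violators_fes):
        roster.append(("FESm" if i % 2 == 0 else "FESf", True))
    for i in range(cohort_spec.violators_hc):
        roster.append(("HCm" if i % 2 == 0 else "HCf", True))

    rows: list[dict] = []
    series_list: list[BoldSeries] = []
    traces: dict[str, MotionTrace] = {}
    child_seeds = ss.spawn(len(roster) * 2)

    # pre-draw per-subgroup clinical latents and scores for patients
    by_subgroup: dict[str, list[int]] = {sg: [] for sg in SUBGROUPS}
    for idx, (sg, _) in enumerate(roster):
        by_subgroup[sg].append(idx)
    latents_by_idx: dict[int, dict[str, float]] = {}
    scores_by_idx: dict[int, dict[str, float]] = {}
    for sg in ("FESm", "FESf"):
        idxs = by_subgroup[sg]
        n = len(idxs)
        if n == 0:
            continue
        latents = {
            c.roi_label: table_rng.standard_normal(n)
            for c in effect_spec.clinical_couplings
        }
        scores = _clinical_scores(
            table_rng, sg, n, effect_spec.clinical_couplings, latents
        )
        for j, idx in enumerate(idxs):
            latents_by_idx[idx] = {k: float(v[j]) for k, v in latents.items()}
            scores_by_idx[idx] = {k: float(v[j]) for k, v in scores.items()}

    treated_quota = {"FESm": cohort_spec.treated_male, "FESf": cohort_spec.treated_female}
    treated_used = {"FESm": 0, "FESf": 0}

    for idx, (sg, violator) in enumerate(roster):
        sid = f"sub-{idx + 1:04d}"
        diagnosis = "FES" if sg.startswith("FES") else "HC"
        sex = "male" if sg.endswith("m") else "female"
        col = SUBGROUPS.index(sg)
        row: dict = {
            "subject_id": sid,
            "diagnosis": diagnosis,
            "sex": sex,
            "subgroup": sg,
            "violator": violator,
        }
        for name, spec in _DEMOGRAPHICS.items():
            (mean, sd), (lo, hi) = spec[col], spec[4]
            row[name] = float(_truncated_normal(table_rng, mean, sd, lo, hi, 1)[0])
        if diagnosis == "FES":
            row.update(scores_by_idx.get(idx, {}))
            treated = (not violator) and treated_used[sg] < treated_quota[sg]
            if treated:
                treated_used[sg] += 1
            row["treated_flag"] = bool(treated)
        else:
            for name in _CLINICAL:
                row[name] = np.nan
            row["treated_flag"] = False

        trace = generate_motion_trace(
            cohort_spec.n_volumes, violator, child_seeds[2 * idx]
        )
        traces[sid] = trace
        mt, mr = summarize_motion(trace)
        row["mean_translation_mm"] = mt
        row["mean_rotation_deg"] = mr
        rows.append(row)

        if generate_series:
            jitter = None
            if effect_spec.clinical_couplings and idx in latents_by_idx:
                jitter = {
                    c.roi_label: max(
                        1.0 + c.gain * latents_by_idx[idx][c.roi_label], 0.05
                    )
                    for c in effect_spec.clinical_couplings
                }
            series_list.append(
                generate_subject_series(
                    mask,
                    effect_spec,
                    cohort_spec.tr_seconds,
                    cohort_spec.n_volumes,
                    child_seeds[2 * idx + 1],
                    subgroup=sg,
                    subject_id=sid,
                    amplitude_jitter=jitter,
                )
            )

    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    return series_list, traces, cohort
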