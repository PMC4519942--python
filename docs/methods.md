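# Methods

## Scope and data model

The package analyzes resting-state BOLD runs on a fixed voxel grid.
All computation happens inside a binary gray-matter mask with an
invertible voxel→mm affine; per-voxel quantities are stored as flat
vectors in the mask's canonical (C-order) voxel ordering and embedded
into NIfTI volumes only at I/O boundaries. Spatial registration,
slice-timing and rigid-body realignment are out of scope: synthetic
data is generated directly on the common grid, and real inputs are
assumed already normalized to it.

## Temporal preprocessing

Fixed stage order: (1) discard the first 5 volumes (signal
equilibration); (2) nuisance regression; (3) linear detrend; (4) ideal
band-pass 0.01–0.08 Hz. Choices:

- **Nuisance set**: global mean, white-matter mean, CSF mean, and the 6
  motion parameters, extracted *after* the volume discard. An
  intercept is always added (the stated 9-regressor set leaves residual
  means arbitrary otherwise). Rank-deficient designs are pruned column
  by column with a warning rather than failing.
- **WM/CSF analogues**: real pipelines take these means from T1
  segmentations. On synthetic grids, `default_tissue_masks` designates
  the deepest 5 % of the mask interior (by Euclidean distance to the
  border) as the CSF analogue and the 75th–95th depth percentiles as
  the WM analogue. Injected effect regions must avoid these bands —
  regressing a region's own mean removes its signal, which is also true
  of real data when seeds overlap nuisance masks.
- **Band-pass**: an ideal rectangular DFT filter (bins with
  low ≤ k/(nT) ≤ high retained, all others including DC zeroed). It is
  exactly idempotent and exactly invertible on in-band content, which
  makes filter contracts testable to 1e-10. A Butterworth variant was
  deliberately not used.
- **Motion screening**: a subject is excluded iff any volume exceeds
  1.5 mm translation or 1.5° rotation on any single axis (strict
  inequality; per-axis maxima over the run). Motion *summaries* are the
  per-volume Euclidean norms averaged over the run.

## Degree centrality

Degree counts strictly positive correlations above the threshold
(default r > 0.25); negative correlations never count, because global
signal regression shifts the correlation distribution and makes
negative edges uninterpretable. Zero-variance voxels get degree 0 (with
a logged count) and are invisible to other voxels. Standardization is
mask-wise z-scoring with the population SD — a degree count cannot be
atanh-transformed, so the "Fisher Z for standardization" convention of
the REST lineage is implemented as plain z-standardization (atanh is
reserved for correlations in the seed-connectivity stage). Smoothing
(default FWHM 6 mm, σ = FWHM/2.3548 per axis) applies to the
standardized map: convolve in the full grid with zeros outside, then
re-mask, without edge renormalization. The pairwise computation is
blocked (default 2048 voxels per block), so memory stays
O(block × N).

## ALFF

Unnormalized DFT of the full series (no zero padding); amplitude =
√power = |X_k|; ALFF = mean amplitude over bins whose frequency lies in
the closed band interval. Under this convention Σ|X_k|² = n·Σx², which
the tests verify. Maps are divided by the mask mean (so the normalized
map has mask mean exactly 1 before smoothing), then smoothed. The
band-pass in preprocessing already confines power to the band; the ALFF
band average is retained anyway to mirror the conventional pipeline,
and the redundancy is harmless.

## Group model

One OLS fit per voxel with a shared design: intercept, sex (+1 male /
−1 female), diagnosis (+1 FES / −1 HC), their product, and centred
covariates (age by default; age and education for one-sample hub maps).
Effect coding keeps main effects interpretable in the presence of the
interaction. F tests are partial F via full-vs-reduced refits; on
balanced designs without covariates they reduce exactly to the textbook
two-way ANOVA, which the tests check against an independent
sums-of-squares oracle. Post-hoc two-sample t tests (covariate-adjusted,
two-sided, voxel p < 0.001) are evaluated only inside the interaction
F-mask. Degenerate zero-residual voxels yield t = ±∞ with p = 0 rather
than NaN. No variance smoothing or nonsphericity correction is applied.

## Monte-Carlo cluster-extent correction

Per iteration: unit Gaussian noise on the mask grid → Gaussian
smoothing at the *applied* kernel FWHM (no residual-based smoothness
estimation; this slightly biases k and is a documented simplification)
→ re-standardization within the mask (so quantile thresholds are exact)
→ threshold at the z-quantile of the voxel p → largest connected
component. Defaults: connectivity 18 (face + edge, matching a 5-mm
connection radius at 3-mm voxels), one-sided thresholding of the
simulated field (the AlphaSim convention; a two-sided option exists and
lowers k by about one voxel at the whole-brain operating point). The
extent threshold k is the smallest integer whose null exceedance
fraction is strictly below α; declaring clusters of ≥ k voxels then
controls the familywise error at α. On a ~60 000-voxel 3-mm brain-like
ellipsoid with FWHM 6 mm, voxel p < 0.001, α = 0.05 and 1000
iterations, k lands at 12–13 voxels. The max-cluster distribution is
discrete, so the realized FWE sits below α (measured ≈ 0.036 on the
20³ calibration grid); the calibration test checks the [0.03, 0.07]
band with 2000 null + 3000 fresh fields to keep the binomial error of
the estimate well inside the band.

## Seed connectivity

Seed series = unweighted mean over the seed cluster. FC maps are
voxel-wise Pearson r against the seed series; constant voxels get r = 0
with a log entry; Fisher z = atanh of r clipped to ±(1−1e-7) so outputs
stay finite. Group networks: one-sample t on the z maps with age as
covariate, thresholded at the voxel p with the Monte-Carlo extent k;
surviving voxels form the network mask. The default group is healthy
controls only (the configuration can run any group).

## Clinical correlations

ROI means of subject-level DC-z or normalized-ALFF maps are Pearson-
correlated (Spearman optional) with PANSS total and syndrome scores,
per stratum (male patients, female patients, combined). The per-test
threshold is family α divided by the number of ROIs — 0.05/8 = 0.00625,
displayed as 0.006. Results below the uncorrected 0.05 but above the
Bonferroni bar are reported as a distinct "suggestive" tier rather than
silently mixed with the significant ones.

## Synthetic cohort generator

The generator defines the study conditions; everything downstream is
validated against it.

- **Cohort structure** (defaults): included subgroups 61/63/50/52
  (FESm/FESf/HCm/HCf) plus 21 patient and 14 control motion violators
  appended on top (pre-exclusion 145/116; the motion filter recovers
  124/102 exactly), 28 treated patients (15 male / 13 female) among the
  included, 200 volumes at TR = 2 s.
- **Demographics/clinics**: Gaussian around the published group means
  and SDs (ages ≈ 24–25 ± 7 y, PANSS total ≈ 88 ± 17, etc.), clipped at
  instrument bounds (five-factor item ranges for the syndrome scores,
  30–210 for the total). Clipping rather than exact truncated-normal
  sampling: at these means the bounds are several SDs away, so the
  distortion is negligible.
- **Signal model**: voxel series = Σ communities w·latent + a·local +
  σ·white noise, with latents and local fluctuations ideally
  band-limited to 0.01–0.08 Hz and unit-SD. Within-community
  correlation is w²/(w² + a² + σ²) in closed form, which the tests
  verify by simulation. AR(1) temporal structure is deliberately not
  modelled — analytic tractability of the expected correlations was
  preferred.
- **Degree fixtures** partition the *whole* mask into octant
  communities (plus the WM/CSF "deep" band) rather than embedding one
  community in independent noise: binarized degree in narrow-band data
  is otherwise dominated by filter-induced noise correlations, and
  added signal variance *dilutes* a voxel's noise correlations — an
  instructive failure mode that the partitioned design avoids, and
  which mirrors real data being covered by correlated networks
  everywhere.
- **Group×sex effects**: per-subgroup coupling weights or amplitude
  multipliers (e.g. hub coupling 0.2 in FESm vs 1.0 elsewhere for the
  male-selective degree-reduction scenario).
- **Clinical coupling**: a per-subject standard-normal latent u is
  shared between a region's amplitude multiplier (1 + 0.5u, floored)
  and the named PANSS score (ρu + √(1−ρ²)ε on the score's scale), so
  the expected score–amplitude correlation is the target ρ.
- **Motion**: slow random-walk drift plus jitter, capped at 0.4
  mm/degree per axis for non-violators (norm summaries ≈ 0.1, matching
  the published ≈ 0.11–0.13); violators get one spike drawn beyond the
  1.5 limit. Only the violator/non-violator contract is guaranteed.
- **Determinism**: one seed fans out through `numpy` SeedSequence
  spawning; identical seed and spec give bit-identical cohorts.

Not emulated: scanner artifacts, physiological noise, slice-timing
offsets, susceptibility distortion, spatial autocorrelation of the
noise, item-level PANSS structure. Passing recovery tests therefore
demonstrates correctness of the pipeline's statistics under the stated
signal model, not robustness to acquisition artifacts.

## Problem sizes used in the validation suite

Chosen as desk-scale versions of the study conditions: recovery and
calibration fixtures run on 12³–20³ grids (≈ 500–4000 mask voxels) with
12 subjects per cell and 120-volume runs; the interaction-recovery
suite uses 25 cohort replicates; FWE calibration uses 2000 null and
3000 fresh fields on the 20³ grid; clinical-coupling recovery uses 20
replicates at the published male-patient sample size (n = 61). The
Monte-Carlo extent threshold is additionally reproduced at full scale
(61×73×61 grid, ~60 000-voxel mask, 1000 iterations). The full-size
2×2 cohort (261 subjects) is generated tables-only where BOLD volumes
are not needed.

## Known limitations

- Smoothness in the cluster null is the applied kernel, not estimated
  from residuals; with intrinsically smoother data the derived k is
  anti-conservative.
- The ideal band-pass assumes stationarity and exact bin alignment;
  non-integer-period sinusoids leak a few percent of power.
- Mask-edge smoothing attenuates values near the border (no kernel
  renormalization); group comparisons are unaffected because the
  attenuation is identical across subjects.
- Whether the published pipeline standardized degree within the
  gray-matter mask or whole brain is not stated; within-mask is
  implemented and configurable.
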