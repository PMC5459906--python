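# Methods

`rsband` re-implements, as a tested pipeline, a multi-site resting-state fMRI
analysis: voxel-wise ALFF, ReHo and weighted degree centrality in six
frequency bands, group comparison with covariates, standardized-effect-size
(Cohen's d) maps, Monte-Carlo cluster-extent correction, and cross-cohort
overlap/Dice consistency quantification. Because the real multi-site data
requires a large download and external preprocessing, every stage is
exercised end to end on synthetic multi-cohort BOLD data with known injected
effects; this note records the models, conventions and design choices, and
what the synthetic results do and do not establish about real data.

## Voxel-wise metrics

All metrics are computed per subject on a series that has been truncated
(first 10 volumes dropped, next 170 kept) and nuisance-regressed (linear
trend, Friston-24 motion expansion, mean WM and CSF signals; the voxel's
temporal mean is restored after regression so amplitude measures keep a
physical baseline — the convention of the standard resting-state toolchains,
which operate on non-demeaned residual series). The global signal is not
regressed.

**Frequency bands.** conventional 0.01–0.08 Hz and the five sub-bands
Slow-6 (0–0.01), Slow-5 (0.01–0.027), Slow-4 (0.027–0.073),
Slow-3 (0.073–0.198), Slow-2 (0.198–0.25 Hz). Band-pass filtering is an
ideal rectangular filter on the real FFT with half-open bin inclusion
[low, high), so the five sub-bands tile 0–0.25 Hz without double counting;
the Nyquist bin (0.25 Hz at TR = 2 s) belongs to Slow-2 only, and the 0 Hz
bin is always removed.

**ALFF** is the mean of the single-sided amplitude spectrum, normalized as
2|X_k|/N, over the in-band bins of the linearly detrended course. No source
convention fixes the spectrum normalization; since every downstream use is a
group *contrast*, any fixed normalization is equivalent — ours is pinned by
a closed form (amplitude-A sinusoid on an exact in-band bin, m in-band bins
→ ALFF = A/m) asserted in the tests. ALFF is computed on spatially smoothed
data (6 mm FWHM Gaussian).

**ReHo** is Kendall's coefficient of concordance W between a voxel's course
and its in-mask nearest neighbours (27 by default; 19 and 7 supported):
W = (Σ_i R_i² − n R̄²) / ((1/12) K² (n³ − n)), with R_i the rank sum at time
point i, R̄ = (n+1)K/2, K the number of courses and n the time points. Ties
get midranks with no tie-correction term in the denominator (the printed
form of the statistic has none); this understates W for heavily tied data,
which band-passed continuous BOLD does not produce. At mask edges K is the
actual in-mask neighbour count (voxels are not dropped); K < 2 yields a
missing value. ReHo is computed on *unsmoothed* band-passed data and the
resulting map smoothed afterwards.

**Degree centrality (weighted)** is D_i = Σ_j a_ij over all in-mask j ≠ i,
where a_ij is the Pearson correlation kept only when a_ij ≥ 0.2 (the
equation-of-record uses ≥; a `strict` flag switches to >). Negative
correlations are zeroed, not analyzed separately. Correlations stream in row
blocks but are exactly the full-matrix result; a cap (~10⁸ pairs) guards the
desk-scale contract. Like ReHo, DC is computed before smoothing — smoothing
first would manufacture local correlation — and the order is enforced
through the series' processing history: computing ALFF on unsmoothed, or
ReHo/DC on smoothed, provenance-tagged data raises an error.

## Group statistics

Per voxel, ordinary least squares on [intercept, group (ADHD = 1), centered
covariates]; t is the group coefficient over its standard error with
residual df = n − p from the actual design (not n − 2). Covariates are IQ
and Jenkinson mean FD per cohort, plus c−1 cohort dummies in pooled
analyses. FD uses Jenkinson's RMS formulation with an 80 mm sphere:
FD = sqrt(r²/5 · tr(AᵀA) + bᵀb) for the differential rigid transform
T_i T_{i−1}⁻¹ − I. The SES (Cohen's d) map is the exact algebraic rescaling
d = t·√((n₁+n₂)/(n₁n₂)); at d = 0.30 and n = 15/15 this gives t = 0.8216 →
0.822. (For group sizes 29/29, 28/28 and 19/19 the exact values are 1.1424,
1.1225 and 0.9247 — reported equivalents elsewhere differ from these by
~0.001–0.002 in the third decimal; we implement the exact algebra rather
than reverse-engineering a rounding.)

Analysis masks keep voxels present in ≥ 80% of subjects (inclusive at the
boundary: 4 of 5 counts) intersected with the gray-matter mask; the pooled
mask is the intersection of cohort masks.

**Cluster-extent correction.** The minimum cluster size k at corrected
p < 0.05 is calibrated by simulating smooth Gaussian noise on the analysis
mask (the AlphaSim approach): per iteration, iid noise is smoothed to the
target FWHM, standardized within the mask, thresholded two-tailed at the
voxel p, and the largest cluster recorded; k is the smallest integer with
empirical P(max ≥ k) ≤ 0.05. Surviving clusters must be *strictly larger*
than k. Connectivity defaults to 26 (faces+edges+corners; 6 and 18
available). The FWHM fed to the simulation is estimated from GLM residual
maps by the classical spatial-differencing estimator,
FWHM = voxel·√(−2 ln 2 / ln(1 − Δvar/2var)) per axis on standardized
residuals. Positive and negative suprathreshold voxels are clustered
separately; everything is two-tailed.

A practical note on the ordering property (k non-decreasing in FWHM and in
voxel p): it is cleanly visible for voxel p ≤ 0.05. Beyond that the
two-tailed suprathreshold set occupies ≥ 10% of the mask and approaches the
percolation regime, where the max-cluster-size tail quantile fluctuates more
across 500-iteration runs than the setting effect itself; the ordering
checks therefore use FWHM ∈ {3, 6, 9} mm × voxel p ∈ {0.005, 0.02, 0.05}.

## Cross-cohort consistency

Thresholded t- or SES-maps are binarized and overlapped across cohorts. The
Dice coefficient follows the study definition: |intersection of all N maps|
divided by the **sum of all cohorts' map sizes**. This is *not* the
classical 2|A∩B|/(|A|+|B|): for two maps it equals classical Dice / 2, and
its maximum at N maps is 1/N (0.25 for four identical maps) — flagged
prominently because the values are not comparable to classical Dice from
other sources. Per-cluster Dice rows (for clusters overlapped by ≥ 3 or
≥ 4 cohorts) use the cluster's voxel count over the same whole-map
denominator; whether a 3-of-4 cluster should instead be normalized by only
the three overlapping cohorts' totals is not decidable from the source
description, so the all-cohorts reading is the default and both are easy to
compute. Every flagged voxel is also categorized against the pooled map
(pooled-only, k-cohorts-only, pooled+k); the categories partition the union
exactly. Region naming (atlas labels) is out of scope; tables report peak
world coordinates via the affine.

## Synthetic data generator

The generator emulates a four-cohort pediatric dataset: group sizes
29/29, 15/15, 28/28, 19/19 (ADHD/TDC, all male), TR 2 s, 180 volumes
(≥ 180 enforced so that dropping 10 and keeping 170 is always possible),
3 mm isotropic voxels. The default grid is 24³ with an ellipsoidal "brain"
(42% semi-axes); designated WM and CSF blobs sit near the ∓x poles so that
effect ROIs placed centrally never intersect the nuisance-signal masks. The
analysis scripts and calibration use a 20³ grid — identical physics, chosen
so all-pairs DC and the Monte-Carlo suites run at desk scale; problem sizes
are stated with each experiment.

**Baseline noise** is AR(1) Gaussian in time (ρ = 0.3, innovation variance
1−ρ² for unit marginal variance — the minimal temporally autocorrelated
BOLD stand-in), spatially smoothed to 4 mm FWHM, then renormalized to unit
temporal SD per voxel (so injection scales are in baseline-SD units) and
offset by a baseline of 100. Everything is a pure function of (spec, seed);
per-subject streams derive from SeedSequence hashing of (master seed,
subject index). Simulation runs in float32 — ample for a noise model — while
metric maps and statistics are float64.

**Injected effects.** Three mechanisms, each leaving voxels outside its
target set bit-identical:

* *amplitude (ALFF)*: independent band-limited signal (flat in-band
  spectrum) of SD `scale` added to ROI voxels. Because the additions are
  independent across voxels, they also *decorrelate* neighbours — an
  amplitude injection carries a negative ReHo (and mildly negative DC) side
  effect at its ROI. This crosstalk is intrinsic to any non-shared additive
  amplitude model and is visible in the demo analysis;
* *local coupling (ReHo)*: one shared band-limited course mixed into all ROI
  voxels as √(1−c²)·x + c·u, with the mixture renormalized to each voxel's
  original mean and SD — per-voxel variance is preserved exactly (pure
  synchrony, no amplitude confound), c = 0 is the identity and c = 1 makes
  all ROI courses rank-identical (W = 1);
* *hub connectivity (DC)*: the same variance-preserving mix applied to a hub
  ROI and a seeded random fraction of distant in-mask voxels.

**Calibration.** EffectSpec takes a target Cohen's d; closed forms linking
coupling/scale to the realized d of KCC or DC are intractable, so the
mapping is measured by simulation (two groups differing only in the
injection, full metric pipeline, ROI-mean per-voxel d; 16/16 subjects,
20³ grid, 10 mm ROI, two seeds per grid point) and frozen as a monotone
lookup table in `src/rsband/data/calibration.json`
(`analysis/00_calibrate_effects.py` regenerates it). Inversion is by
interpolation with linear extrapolation beyond the measured range, clamped
to [0, 1] for couplings. Calibration is approximate by construction: the
realized d drifts with ROI size (edge dilution under 6 mm smoothing),
grid, and band; recovery checks therefore carry a ±0.3 tolerance around the
designed d.

**Covariates.** IQ ~ N(105, 13²) for ADHD and N(118, 13²) for TDC; motion is
a random-walk in the six rigid-body parameters rescaled per subject so its
Jenkinson mean FD hits a target drawn from N(0.15, 0.04²) mm (ADHD) or
N(0.12, 0.04²) mm (TDC) — lower IQ and more motion in the patient group, as
in the real cohorts, giving the GLM genuine nuisance structure.

**What the generator does not model:** hemodynamic response convolution,
physiological (cardiac/respiratory) noise, scanner drift and artifacts,
anatomical variability, registration error, or site differences beyond
sample size. Passing tests therefore establish the *computational*
correctness and calibration of the pipeline (correct formulas, controlled
false positives on its own noise model, recovery of designed effects), not
that the pipeline's operating characteristics transfer quantitatively to
real BOLD data.

## Numerical choices and degenerate inputs

* Nuisance regression uses the pseudo-inverse (rank-deficient designs allowed);
  collinear *group* designs are rejected, naming the redundant columns.
* Voxels with numerically zero residual variance (identical data in both
  groups) get t = 0 rather than 0/0 noise.
* Constant time courses in DC contribute zero correlations (logged warning,
  not an error); K < 2 neighbourhoods in ReHo give missing values.
* Smoothing of metric maps is mask-normalized (kernel renormalized over the
  in-mask support) to avoid edge bleed; BOLD series are smoothed without
  mask normalization, volume by volume.
* The smoothness estimator reports an axis as missing with < 2 in-mask
  neighbour pairs and clamps to 0 when the neighbour correlation is ≤ 0
  (effectively unsmoothed data).
* FD offset invariance: exact for translation offsets; first-order for
  rotation offsets (the differential transform of finite rotations does not
  commute) — the property tests reflect this.

## Problem sizes used by the test and acceptance suites

Null calibration: 100 analyses (40 in the faster acceptance script) of
20+20 subjects on a 20³ grid, conventional band, voxel p 0.05, k from
1000-iteration Monte Carlo. Recovery: d = 1.2, 20 seeds (10 in the script)
at the same size; the d = 0.8 generator check uses 10 seeds. Ordering: 3×3
settings × 500 iterations. Overlap regimes: 4 cohorts × 14+14 subjects × 2
regimes. These sizes are the package's own desk-scale choices and are
printed in each experiment's output.

## Known limitations

* The calibration table is tied to the default pipeline (conventional band,
  6 mm smoothing, 170 volumes); requesting effects in other bands or with
  other smoothing reuses it and will realize a somewhat different d.
* The study-variant Dice is intentionally non-classical (see above).
* Cluster-extent correction assumes stationary Gaussian smoothness; the
  differencing estimator is biased upward on very coarse grids.
* SPM-side preprocessing (slice timing, realignment, segmentation, spatial
  normalization) is out of scope — inputs are assumed already aligned, as
  the synthetic data is by construction.
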