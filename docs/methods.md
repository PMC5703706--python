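# Methods

## Model

The package treats the systemic low-frequency oscillation (sLFO) as a
virtual intravascular tracer.  The working model is that each brain
voxel's band-limited BOLD fluctuation is a time-shifted copy of one
common waveform $s(t)$:

$$y_v(t) = a\,s(t + \delta_v) + \varepsilon_v(t),$$

where $\delta_v$ is the voxel's position (in seconds) along the vascular
tree and $\varepsilon$ is noise.  Positive $\delta_v$ means the voxel
sees the waveform *before* the global mean does — the upstream, arterial
side; negative $\delta_v$ marks venous territory, and a region's mean
lag is its "relative drainage time".  The estimator is the discrete
cross-correlation peak against the global mean signal on a ±7 s / 0.5 s
grid.  The 14 s correlation window is matched to the 0.008–0.07 Hz
passband: the slowest in-band period is ~14 s, so the peak is unique
within the window.

Assumptions this model makes, and their consequences:

- **Pure time shift, no dispersion.** Real blood transit disperses the
  waveform; the phantom propagates it undistorted so ground truth stays
  exact.  Passing tests therefore validate the estimator and pipeline
  mechanics, not robustness to dispersion.
- **Common waveform.** Neurovascular (stimulus-driven) components and
  regionally heterogeneous physiology are not modelled.
- **Global mean as reference.** The reference is computed from the
  brain-masked, fully preprocessed data itself.  A consequence worth
  knowing: when a region's delay changes between sessions (the tap-test
  analogue), the global mean moves by *(region fraction) × shift*, so
  the measured regional change is slightly smaller than the injected one
  (≈2.3 s measured for 2.5 s injected with the default ~4% target
  region).  This is a property of global-reference lag mapping itself,
  not an implementation artifact, and is left uncompensated.

## Failure and QC rules

Voxels whose correlogram peaks at the ±7 s boundary, or whose peak
correlation is negative, cannot be tracked unambiguously; they are
assigned the sentinel lag −7 s and flagged `valid=False`.  The sentinel
is preserved in the written maps for fidelity with established practice,
but all group statistics exclude invalid voxels — carrying −7 s into a
mean or a t-test would corrupt it.

A whole map is rejected when its lag histogram collapses into a narrow
zero peak (more than 60% of in-mask voxels within ±0.5 s by default):
this is the signature of tracking failure, typically from excessive
motion, where every voxel locks onto the global signal.  The 0.6
threshold is a configurable operationalization of a qualitative rule; on
phantoms with realistic delay spread the zero-peak fraction is ~0.3, and
a fully collapsed map scores 1.0, so the decision is insensitive to the
exact value.

## Preprocessing choices

Order is fixed and enforced (discard → slice timing → scrub → band-pass
→ resample); running stages out of order raises an error rather than
silently producing biased lags.

- **Initial discard**: 10 s (ceil(10/TR) volumes) for signal
  equilibrium.
- **Slice timing**: cubic-spline interpolation of each slice to the
  reference slice's acquisition times.  At ≤0.07 Hz the interior spline
  error for TR 2 s is <10⁻³ of signal amplitude — far below the 0.5 s
  lag quantum (slice offsets up to one TR would otherwise alias directly
  into the lag map, which is why this stage matters here more than in
  activation studies).
- **Scrubbing**: the ±3 mm / ±3° per 0.5 s criterion is read literally
  as a *rate*: frame-to-frame deltas are scaled by 0.5/TR before
  thresholding (a 13 mm jump at TR 2 s → 3.25 mm/0.5 s → flagged; 5 mm
  → 1.25 → passes).  Setting `rate_window=TR` thresholds raw deltas
  instead, for users who prefer that reading.  Flagged volumes are
  replaced by linear interpolation between the nearest clean neighbours
  (nearest-neighbour extension at the edges); a series with fewer than
  two clean volumes is rejected as unusable.
- **Band-pass**: 4th-order Butterworth 0.008–0.07 Hz applied
  forward–backward.  Zero phase is non-negotiable: any group delay adds
  a constant bias to every lag.  One octave outside the band the
  amplitude response is below 10%.
- **Resampling**: cubic spline onto a 0.5 s grid.  For in-band signals
  the error is <1% of amplitude.

## Synthetic data

`default_phantom_spec()` mirrors a patient acquisition at desk scale:
16×16×8 voxels of 3 mm, TR 2.0 s, 180 volumes (6 min), ascending slice
timing, sLFO band 0.008–0.07 Hz.  The sLFO is a flat-spectrum sum of
Fourier harmonics inside the band, evaluable in closed form at any time
point, so voxel series at arbitrary (off-grid) delays carry no
interpolation error and the 0.5 s resampling is genuinely exercised.
The scan-duration floor (n·TR ≥ 180 s) reflects the established minimum
for reliable lag extraction.

`default_ground_truth()` supplies, on an ellipsoidal brain mask
(~856 voxels):

- a base delay field: an antisymmetric left–right gradient spanning
  ±4 s, exactly mean-zero (so the global reference has zero net phase);
- a **target** region (~4% of the mask, central): lag shifted
  −2.5 s (downstream; shortened drainage) in the post session;
- a **deep** region (13%): age slope +0.05 s/yr (drainage extends with
  age); a **superficial** region (16%, two para-midline blobs): age
  slope −0.05 s/yr.  The small size imbalance leaves a ~0.001 s/yr
  global drift, an order of magnitude below the regression's standard
  error.

Cohorts add smooth between-subject jitter (SD 0.5 s), per-session
scan-rescan jitter (SD 0.3–0.4 s, emulating test-retest variability of
lag estimates), uniform ages, and random sex labels.  Ages are centred
at the range midpoint before multiplying the slope field so that default
slopes cannot push delays outside the trackable ±7 s; the regression's
intercept absorbs the centring and the slope is unaffected.  Noise SD
defaults to 1.0 relative to unit signal amplitude (SNR 1) — a
conservative choice, since the patient-data signal-to-noise of the sLFO
is not well characterized; the paired-cohort analyses use SNR 2
(noise SD 0.5), where scan-level estimation noise rather than raw SNR
dominates the group statistics.

What the phantom does *not* emulate: hemodynamic response functions and
neurovascular coupling, cardiac/respiratory physiological noise,
dispersion of the sLFO along the tree, susceptibility artifacts, and
image-content motion corruption (spikes perturb only the motion trace,
because scrubbing consumes parameters, not images).  Tests passing on
these phantoms demonstrate correctness of the computation, not clinical
performance.

## Group statistics

- **Smoothing**: Gaussian, FWHM 6 mm, receiver-normalized over the valid
  mask so invalid voxels neither contribute nor receive.  This preserves
  constant fields exactly; the in-mask mean of a non-constant field
  drifts slightly near mask boundaries (empirically <2% of the in-mask
  SD on the default mask) — exact simultaneous preservation of both is
  mathematically impossible for a renormalized kernel.
- **Paired contrast**: per-voxel paired t on (post − pre), height
  threshold p<0.005 (one-sided per direction; both directions always
  computed), cluster-level inference by sign-flipping permutation of the
  maximum cluster statistic — exhaustive (all 2ⁿ) for n ≤ 12.  The
  *cluster mass* (sum of suprathreshold t) is the default statistic.
  Extent is available (`cluster_stat="extent"`) but not default: under
  exhaustive sign flipping a strong homogeneous effect yields nearly the
  same suprathreshold footprint for the identity and for every
  single-subject flip, so the corrected p of extent has a floor of about
  2(n+1)/2ⁿ (~0.006 at n=11) regardless of effect size; mass separates
  these patterns by magnitude and reaches 1/2ⁿ.  A design with too few
  subjects to attain the requested cluster p (e.g. 2 pairs vs p<0.005)
  is rejected up front.
- **ROI phase**: mean lag over valid ROI voxels per subject; Welch's
  t-test between groups, paired t within subjects.
- **Age regression**: voxel-wise OLS on [intercept, age, sex(binary)],
  two-sided t for age, BH-FDR at q=0.05 across jointly-valid in-mask
  voxels, then face-connected clusters smaller than the minimum size are
  discarded.  The canonical threshold is 200 voxels *at 2 mm isotropic*;
  `cluster_voxels_for_volume` keeps the 1.6 mL volume criterion fixed
  across voxel sizes (59 voxels at 3 mm).  Positive and negative age
  effects are reported as separate cluster sets.  Voxel-wise
  patient-vs-control contrasts are deliberately not offered (cross-group
  anatomical alignment is outside this package's scope).
- **Connectivity** is 6-neighbour (face) everywhere; tie-breaking in lag
  selection prefers the smallest |τ| and resolves ±τ ties toward the
  venous (negative) side — both documented conventions where the
  literature is silent.

## Numerical conventions and degenerate inputs

- Correlations use overlap-only samples (no zero padding); at the
  extreme ±7 s shifts the overlap is the series length minus 14 s, and
  series with fewer than 8 overlapping samples are rejected.
- A constant reference, an empty mask, an all-flagged motion trace, a
  rank-deficient design matrix (the collinear columns are named), and
  ROIs without valid voxels all raise typed errors rather than NaNs.
- Paired t-statistics with zero variance map to 0 (zero mean) or ±∞
  (nonzero); infinite t is capped at 10⁴ inside cluster masses so
  comparisons stay well defined.
- Pipeline outputs are written as uncompressed NIfTI and hashed into a
  manifest; two runs with the same config and seed are byte-identical.

## Problem sizes

Desk-scale sizes were chosen so a full synthetic study (phantom
generation → preprocessing → lag maps → all three analyses) completes in
seconds per subject on one CPU: 16×16×8 grids, 180 volumes, cohorts of
11 pairs (patients) and 40 singles (controls), exhaustive 2¹¹
permutations for the paired contrast.  The statistics scale unchanged to
full-resolution maps; only memory and wall time grow.

## Known limitations

- The global-reference coupling described above slightly attenuates
  measured regional changes; alternatives (external NIRS reference,
  iterative re-referencing) are out of scope.
- Sub-grid (parabolic) peak interpolation, recursive regional-reference
  tracking, and dispersion modelling are not implemented.
- The motion-rate criterion's original raw-vs-normalized reading is
  ambiguous; both are supported, the rate reading is default.
- Sex enters the regression as a binary main effect only; no
  interactions.
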