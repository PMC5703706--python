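# lagflow

**BOLD lag mapping:** tracking the systemic low-frequency oscillation
(sLFO) through the brain vasculature from resting-state fMRI, with the
temporal preprocessing the technique requires, group-level statistics,
and a synthetic phantom generator that makes every stage verifiable
against exact ground truth.

## The problem and who this is for

The BOLD signal carries a low-frequency (0.008–0.07 Hz) oscillation of
systemic origin — a fluctuation of hemoglobin content that travels with
the blood.  Because every voxel sees the same waveform, time-shifted by
its position in the vascular tree, the *relative phase* of this
oscillation acts as an intrinsic tracer of cerebral perfusion: voxels
that lead the global mean signal sit upstream (arterial side), voxels
that trail it sit downstream (venous side).  Mapping this per-voxel lag
("relative drainage time") has been used to study venous drainage changes
in normal pressure hydrocephalus and in normal aging, where the deep and
superficial venous systems dissociate.

`lagflow` is for neuroimaging researchers who want a tested, scriptable
implementation of this analysis: per-voxel lag maps from preprocessed 4D
NIfTI data, plus the group statistics used in pre/post intervention and
aging-cohort designs.  Since clinical datasets of this kind are not
openly deposited, the package ships a phantom generator whose delay
fields are exact ground truth, so the whole chain is verifiable offline.

## Method

For each in-mask voxel $v$ with time course $y_v(t)$ and the global mean
reference $r(t)$ (unweighted mean over in-mask voxels, demeaned), the lag
is

$$\hat\tau_v = \arg\max_{\tau \in \{-7, -6.5, \dots, +7\}\,\mathrm{s}}
\; \mathrm{corr}\left[y_v(t),\, r(t+\tau)\right],$$

computed over overlapping samples on a 0.5 s grid, with positive $\tau$
assigned to voxels that *lead* the reference (upstream/arterial).
Voxels whose correlogram peaks at the ±7 s boundary or whose peak
correlation is negative are ambiguous: they receive the sentinel value
−7 s and are flagged invalid.

Around this core:

- **Preprocessing** (fixed order, enforced): discard of the first 10 s,
  slice-timing correction, motion scrubbing (±3 mm / ±3° per 0.5 s,
  linear interpolation of flagged volumes), zero-phase 0.008–0.07 Hz
  band-pass (4th-order Butterworth, forward–backward), cubic-spline
  resampling to the 0.5 s lag-tracking grid.
- **Group statistics**: voxel-wise paired t-test on smoothed (FWHM 6 mm)
  lag maps with sign-flipping permutation cluster inference (height
  p<0.005, cluster p<0.005, exhaustive for n≤12); ROI phase comparison
  (Welch / paired t); voxel-wise OLS of lag on [intercept, age, sex]
  with Benjamini–Hochberg FDR (q=0.05) and removal of clusters smaller
  than 200 voxels at 2 mm (1.6 mL, converted to the map's voxel size).
- **Phantoms**: band-limited sLFO propagated by pure time shift through a
  delay field with a "periventricular" region whose lag shifts 2.5 s
  downstream between sessions (CSF tap-test analogue) and deep /
  superficial regions with ±0.05 s/yr age slopes.

## Worked example

```python
import numpy as np
import lagflow as lf

truth = lf.default_ground_truth()                  # exact delay field, s
spec = lf.default_phantom_spec(noise_sd=1.0)       # TR 2 s, 180 vols, SNR 1
series, motion = lf.synthesize_subject(spec, truth, session="single")
clean, report = lf.run_preprocessing(series, motion)
lagmap = lf.compute_lagmap(clean)

sel = truth.mask & lagmap.valid
err = np.abs(lagmap.lag[sel] - truth.delay_field[sel])
print(f"mean |lag error|: {err.mean():.3f} s")
print(f"deep-region phase: {lf.relative_phase(lagmap, truth.regions['deep']):+.2f} s")
```

prints (seed 0):

```
mean |lag error|: 0.352 s
deep-region phase: +0.05 s
```

The mean error is below one 0.5 s grid step even at SNR 1 — the band-pass
rejects most of the white noise — and the deep region's phase is near the
global mean for this base delay field (its aging/tap-test shifts are what
the group statistics detect).  The `examples/` directory has one short
script per capability: single-subject lag mapping, the pre/post paired
contrast, the aging regression, and scrubbing/QC.

A thin CLI covers shell use: `lagflow all --config run.yaml` runs a full
synthetic study (see `src/lagflow/data/demo.yaml`), and
`lagflow lagmap bold.nii --mask mask.nii` maps an already-preprocessed
scan.

## Layout

```
src/lagflow/
  containers.py   BoldSeries, MotionTrace (NIfTI / motion-text I/O)
  phantom.py      sLFO generator, PhantomSpec, GroundTruth, cohorts
  preprocess.py   discard / slice timing / scrub / band-pass / resample
  lagmap.py       global reference, lag estimation, QC, ROI phase
  stats.py        smoothing, paired contrast, ROI tests, age regression
  pipeline.py     config-driven end-to-end runs with hashed manifests
  cli.py          `lagflow` command group
docs/methods.md   model, assumptions, parameter choices, limitations
```
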