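"""Build a synthetic subject, preprocess it, and recover its lag map.

A band-limited systemic oscillation (0.008-0.07 Hz) is propagated through
a 16x16x8 phantom brain with a known per-voxel delay field, sampled at
TR 2 s for 6 minutes with noise at SNR 1, then pushed through the full
temporal pipeline (discard, slice timing, scrubbing, zero-phase band-pass,
0.5 s resampling) and cross-correlated against the global mean signal.
"""

import numpy as np

import lagflow as lf

truth = lf.default_ground_truth()
spec = lf.default_phantom_spec(noise_sd=1.0, seed=0)

series, motion = lf.synthesize_subject(spec, truth, session="single")
clean, scrub_report = lf.run_preprocessing(series, motion)
lagmap = lf.compute_lagmap(clean)

sel = truth.mask & lagmap.valid
err = np.abs(lagmap.lag[sel] - truth.delay_field[sel])
qc = lf.lag_histogram_qc(lagmap)

print(f"in-mask voxels:            {truth.mask.sum()}")
print(f"valid (trackable) voxels:  {sel.sum()}")
print(f"mean |lag error|:          {err.mean():.3f} s")
print(f"within one 0.5 s step:     {100 * (err <= 0.5).mean():.1f} %")
print(f"QC zero-peak fraction:     {qc.zero_peak_fraction:.2f} (failed={qc.failed})")
# The lag error stays well inside one 0.5 s grid step at SNR 1: the
# band-pass concentrates the sLFO while suppressing most of the white
# noise, so the cross-correlation peak is rarely displaced.
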