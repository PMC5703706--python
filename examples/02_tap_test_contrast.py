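"""Paired pre/post analysis: detecting a regional drainage-time change.

Eleven synthetic patients are scanned twice; between sessions the
periventricular target region's lag shifts 2.5 s downstream (drainage
time shortens, as after CSF removal).  Per-subject lag maps are smoothed
(FWHM 6 mm) and entered into a voxel-wise paired t-test with sign-flipping
cluster-level inference (all 2^11 sign assignments, height p<0.005,
cluster p<0.005).
"""

import numpy as np

import lagflow as lf
from lagflow import stats as gs

truth = lf.default_ground_truth()          # shift_field = -2.5 s in the target
spec = lf.default_phantom_spec(noise_sd=0.5)
cohort = lf.synthesize_cohort(
    n_subjects=11, truth=truth, spec=spec, paired=True, seed=1, age_range=(70, 85)
)

maps = {"pre": [], "post": []}
for entry in cohort.subjects:
    for sess in ("pre", "post"):
        series, motion = entry[sess]
        clean, _ = lf.run_preprocessing(series, motion)
        maps[sess].append(lf.compute_lagmap(clean))

target = truth.regions["target"]
shift = np.mean([
    lf.relative_phase(post, target) - lf.relative_phase(pre, target)
    for pre, post in zip(maps["pre"], maps["post"])
])

vs = np.full(3, spec.voxel_size_mm)
joint = np.logical_and.reduce([m.valid for m in maps["pre"] + maps["post"]])
pre_s = [gs.smooth_gaussian(m.lag, 6.0, vs, joint) for m in maps["pre"]]
post_s = [gs.smooth_gaussian(m.lag, 6.0, vs, joint) for m in maps["post"]]
result = gs.paired_contrast(pre_s, post_s, mask=joint, affine=spec.affine)

print(f"measured target-region shift: {shift:+.2f} s (negative = downstream)")
print(f"shortened-drainage contrast:  {result.decrease.n_significant} significant cluster(s)")
print(result.decrease.table[["size", "mass", "peak_stat", "p_corr", "significant"]])
print(f"reverse contrast:             {result.increase.n_significant} significant cluster(s)")
# The measured shift is slightly smaller than the injected 2.5 s because
# the global-mean reference itself moves a little when a region's lag
# changes; the significant cluster covers the target region, and the
# reverse contrast stays empty.
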