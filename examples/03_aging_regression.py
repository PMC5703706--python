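"""Voxel-wise age regression: deep vs superficial drainage dissociation.

Forty synthetic controls aged 20-80 carry opposite age trends: drainage
time extends with age (+0.05 s/yr) in the deep periventricular region and
shortens (-0.05 s/yr) in the superficial region.  Lag maps from the full
pipeline enter a per-voxel OLS on [intercept, age, sex] with BH-FDR
(q=0.05) and removal of clusters below the canonical 1.6 mL volume.
"""

import numpy as np

import lagflow as lf
from lagflow import stats as gs

truth = lf.default_ground_truth()
spec = lf.default_phantom_spec(noise_sd=1.0)
cohort = lf.synthesize_cohort(
    n_subjects=40, truth=truth, spec=spec, seed=2, age_range=(20, 80)
)

maps = []
for entry in cohort.subjects:
    series, motion = entry["single"]
    clean, _ = lf.run_preprocessing(series, motion)
    maps.append(lf.compute_lagmap(clean))

min_cluster = gs.cluster_voxels_for_volume(1600.0, spec.voxel_size_mm)
reg = gs.age_regression(maps, cohort.design, fdr_q=0.05, min_cluster=min_cluster)

deep, sup = truth.regions["deep"], truth.regions["superficial"]
pos, neg = reg.positive.significant_mask(), reg.negative.significant_mask()
print(f"min cluster size:        {min_cluster} voxels (1.6 mL at 3 mm)")
print(f"deep-region age slope:   {reg.beta_age[deep & reg.valid].mean():+.3f} s/yr")
print(f"superficial age slope:   {reg.beta_age[sup & reg.valid].mean():+.3f} s/yr")
print(f"positive-effect cluster coverage of deep:        {(pos & deep).sum()}/{deep.sum()}")
print(f"negative-effect cluster coverage of superficial: {(neg & sup).sum()}/{sup.sum()}")

# ROI confirmation: elderly half vs young half of the cohort
groups = np.where(cohort.design["age"] <= cohort.design["age"].median(),
                  "young", "elderly")
roi = gs.roi_group_compare(
    maps, deep, cohort.design.assign(group=groups), ("elderly", "young")
)
print(f"deep-ROI phase, elderly - young: {roi.difference:+.2f} s (p = {roi.p:.2g})")
# Positive difference = the deep region sits further upstream in the
# elderly: its venous drainage is delayed relative to the global phase.
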