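"""Voxelwise scaling-factor harmonization, end to end.

Simulates a paired-coil cohort, splits it into matched template and
validation halves, estimates the 32CH/8CH scaling field on the template,
applies it to the validation 8CH images, and re-runs the paired inference
before and after.
"""

import numpy as np

from coilbias.harmonize import (apply_scaling, estimate_scaling, split_cohort,
                                validate_harmonization)
from coilbias.synthetic import CohortConfig, make_cohort

# acquisition-like resolution: 2 mm voxels, so the 5 mm median window
# spans 3 voxels and actually filters
cohort = make_cohort(20, CohortConfig(grid_shape=(64, 64, 64), voxel_mm=2.0),
                     seed=11)
template, validation, report = split_cohort(cohort, n_template=12, seed=0)
print("split:", {g: (r["n"], round(r["mean_age"], 1), r["n_female"])
                 for g, r in report.items()}, "(n, mean age, females)")

field = estimate_scaling(template, "t1")
truth = cohort[0].truth["gain_32ch"] / cohort[0].truth["gain_8ch"]
rms = np.sqrt(np.mean((field.ratio - truth)[field.valid_mask] ** 2))
print(f"scaling field: ratio range "
      f"[{field.ratio[field.valid_mask].min():.2f}, "
      f"{field.ratio[field.valid_mask].max():.2f}], "
      f"RMS error vs true gain ratio {rms:.4f}")

mask = cohort[0].phantom.brain_mask
rep = validate_harmonization(validation, field, mask, n_perm=300, seed=2,
                             template_set=template)
s = rep.summary()
print(f"validation, pre-scaling:  {s['pre_sig_pos'] + s['pre_sig_neg']:5d} "
      f"significant voxels (coil bias detected)")
print(f"validation, post-scaling: {s['post_sig_pos'] + s['post_sig_neg']:5d} "
      f"significant voxels")

print("\nThe coil difference here is purely multiplicative (gain), so "
      "multiplying the 8CH images by the median-filtered template ratio "
      "restores the paired test to its null.")
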