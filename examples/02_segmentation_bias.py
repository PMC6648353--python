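"""How a coil-dependent contrast shift moves tissue segmentations.

Segments a small cohort acquired under both coils, with a gray/white
contrast shift injected on the 8-channel side, and shows the signature of
contrast-driven misclassification: paired GM and WM difference maps that
anti-correlate at tissue boundaries.
"""

import numpy as np

from coilbias.synthetic import CohortConfig, make_cohort
from coilbias.vbm import segment_tissues, smooth_gaussian

VOX = 4.0

cohort = make_cohort(6, CohortConfig(contrast_shift_8ch=0.05,
                                     noise_sigma_8ch=15.0,
                                     noise_sigma_32ch=15.0), seed=30)

gm_diffs, wm_diffs = [], []
for s in cohort:
    smoothed = {}
    for coil in ("8ch", "32ch"):
        seg = segment_tissues(getattr(s, f"t1_{coil}"), s.phantom.brain_mask,
                              voxel_mm=VOX)
        smoothed[coil] = {t: smooth_gaussian(seg.pv_maps[t], 3.0, VOX)
                          for t in ("gm", "wm")}
    gm_diffs.append(smoothed["32ch"]["gm"] - smoothed["8ch"]["gm"])
    wm_diffs.append(smoothed["32ch"]["wm"] - smoothed["8ch"]["wm"])

gm_d, wm_d = np.mean(gm_diffs, axis=0), np.mean(wm_diffs, axis=0)
ph = cohort[0].phantom
boundary = (ph.pv_gm > 0.1) & (ph.pv_wm > 0.1)
r = np.corrcoef(gm_d[boundary], wm_d[boundary])[0, 1]

print(f"subjects: {len(cohort)}, GM/WM boundary voxels: {boundary.sum()}")
print(f"mean |GM difference| on boundary: {np.abs(gm_d[boundary]).mean():.4f}")
print(f"mean |WM difference| on boundary: {np.abs(wm_d[boundary]).mean():.4f}")
print(f"voxelwise correlation of GM vs WM difference maps: r = {r:+.2f}")

print("\nSame anatomy in both acquisitions: the injected contrast shift "
      "moves boundary voxels across class posteriors, so wherever the "
      "apparent GM volume rises, WM falls (negative correlation) — "
      "hardware bias masquerading as anatomy.")
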