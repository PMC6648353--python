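"""Paired TFCE/FWE permutation inference on a known injected effect.

Creates 20 paired map sets whose second condition carries a +5% effect in
a known cube, runs the sign-flip max-TFCE test, and reports detection
overlap, effect size and percent change.
"""

import numpy as np
from scipy import ndimage

from coilbias.stats import permutation_fwe

SHAPE = (16, 16, 16)
mask = np.ones(SHAPE, bool)
region = np.zeros(SHAPE, bool)
region[5:11, 5:11, 5:11] = True

rng = np.random.default_rng(0)
base = 100.0 + 2.0 * ndimage.gaussian_filter(
    rng.standard_normal((20,) + SHAPE), 1.0)
maps_a = list(base)
maps_b = [x * np.where(region, 1.05, 1.0)
          + 0.5 * ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.0)
          for x in base]

res = permutation_fwe(maps_a, maps_b, mask, n_perm=1000, seed=1)
inter = (res.sig_mask_pos & region).sum()
dice = 2 * inter / (res.sig_mask_pos.sum() + region.sum())
print(f"permutations: {res.n_permutations} "
      f"({'full enumeration' if res.enumerated else 'sampled sign flips'})")
print(f"significant voxels (pos): {res.sig_mask_pos.sum()} "
      f"(injected region: {region.sum()}), Dice overlap {dice:.2f}")
if res.effect_pos:
    print(f"effect size (paired d): {res.effect_pos.effect_size:.2f}, "
          f"percent change: {res.effect_pos.pct_change:+.2f}% "
          f"(injected: +5%)")
print(f"negative direction: {res.sig_mask_neg.sum()} voxels (expect 0)")

print("\nTFCE aggregates spatially extended signal without a cluster "
      "threshold; the max-statistic null over sign flips controls the "
      "family-wise error across all voxels.")
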