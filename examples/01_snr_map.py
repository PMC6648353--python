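"""ROI-wise SNR maps for the two coil profiles.

Simulates a proton-density-like slice (flat tissue contrast, so the map
shows coil gain rather than anatomy) plus a noise-only image for each
coil, and summarizes SNR over brain-covering ROIs by region.
"""

import numpy as np

from coilbias.snr import roi_partition, snr_map
from coilbias.synthetic import (make_coil_profile, make_tissue_phantom,
                                simulate_t1)

GRID, VOX, ROI = (32, 32, 32), 4.0, 4

phantom = make_tissue_phantom(
    GRID, VOX, seed=5,
    tissue_means={"csf": 800.0, "gm": 800.0, "wm": 800.0})
mid = GRID[2] // 2
# ROIs that are mostly brain (air ROIs would swamp the regional summary);
# slices transposed so rows run posterior -> anterior
brain_roi = roi_partition(phantom.brain_mask[:, :, mid].T.astype(float),
                          ROI).mean(axis=(2, 3)) > 0.8

for kind, label in (("eight_ch", "8CH"), ("thirty_two_ch", "32CH")):
    coil = make_coil_profile(kind, GRID, VOX)
    signal = simulate_t1(phantom, coil, seed=1)[:, :, mid].T
    rng = np.random.default_rng(2)
    noise = np.hypot(rng.normal(0, coil.noise_sigma, signal.shape),
                     rng.normal(0, coil.noise_sigma, signal.shape))
    m = snr_map(signal, noise, roi_size=ROI)
    n = m.values.shape[0]
    thirds = {"posterior": slice(0, n // 3),
              "central": slice(n // 3, 2 * n // 3),
              "anterior": slice(2 * n // 3, n)}
    summary = {name: np.nanmean(m.values[sl][brain_roi[sl]])
               for name, sl in thirds.items()}
    cv = np.nanstd(m.values[brain_roi]) / np.nanmean(m.values[brain_roi])
    print(f"{label}: brain-ROI SNR "
          + ", ".join(f"{k}={v:.1f}" for k, v in summary.items())
          + f" | CV={cv:.3f}")

print("\nThe 8CH profile is anterior-high with a central drop; the 32CH "
      "profile is flatter (smaller CV) with its peak posterior. Each ROI "
      "SNR estimates A/sigma via the Rayleigh-SD correction "
      "sqrt(2/(4-pi)).")
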