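"""Dual-regression connectivity and the posterior-coil effect.

Builds resting-state series from known network maps x time courses under
a flat coil and under the posterior-sensitive 32-channel-like profile,
and shows that the posterior network's z-scores rise with the local gain.
"""

import numpy as np

from coilbias.rsfmri import dual_regression, highpass, make_network_templates
from coilbias.synthetic import (CoilProfile, make_coil_profile,
                                make_tissue_phantom, simulate_bold)

GRID, VOX, TR = (32, 32, 32), 4.0, 2.2

phantom = make_tissue_phantom(GRID, VOX, seed=5)
templates = make_network_templates(GRID, VOX, phantom=phantom)
print("networks:", ", ".join(templates.names))

coils = {"flat": CoilProfile("eight_ch", np.ones(GRID), 1.0, VOX),
         "32ch": make_coil_profile("thirty_two_ch", GRID, VOX)}

for name, coil in coils.items():
    series = simulate_bold(phantom, templates, [1.0] * 8, coil,
                           n_volumes=120, tr_s=TR, seed=9, noise_sigma=1.0)
    series = highpass(series, cutoff_hz=0.01, tr_s=TR)
    conn = dual_regression(series, templates)
    post = templates.network_maps[0] > 0.5  # medial visual, posterior
    front = templates.network_maps[5] > 0.5  # executive control, frontal
    print(f"{name:5s} coil: medial-visual z in-network "
          f"{conn.z_maps['medial_visual'][post].mean():5.2f} | "
          f"executive-control z {conn.z_maps['executive_control'][front].mean():5.2f}")

print("\nIdentical physiology in both runs: only the coil gain differs. "
      "The posterior gain peak raises temporal SNR there, inflating the "
      "posterior network's connectivity z-scores.")
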