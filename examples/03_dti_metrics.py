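"""Tensor fitting and the FA analysis mask.

Simulates a noiseless then a noisy diffusion acquisition from a known
tensor field, fits voxelwise tensors by log-linear least squares, and
reports recovery error and FA/MD in white matter.
"""

import numpy as np

from coilbias.dti import analysis_mask, fit_tensor
from coilbias.synthetic import (CoilProfile, make_diffusion_scheme,
                                make_tensor_truth, make_tissue_phantom,
                                simulate_dwi)

GRID, VOX = (32, 32, 32), 4.0

phantom = make_tissue_phantom(GRID, VOX, seed=2)
truth = make_tensor_truth(phantom)
scheme = make_diffusion_scheme()  # 60 directions at b=1000 + one b=0
print(f"scheme: {scheme.n_volumes} volumes, {scheme.n_b0} b=0")

for sigma, label in ((0.0, "noiseless"), (30.0, "sigma=30 (SNR~20)")):
    coil = CoilProfile("eight_ch", np.ones(GRID), sigma, VOX)
    stack = simulate_dwi(phantom, truth, scheme, coil, seed=4)
    fit = fit_tensor(stack, scheme)
    ok = fit.fit_ok
    err = np.abs(fit.tensors()[ok] - truth.d_tensor[ok]).max()
    wm = phantom.pv_wm > 0.95
    print(f"{label:20s} max tensor error {err:.2e} mm^2/s | "
          f"WM median FA {np.median(fit.fa[wm]):.3f}, "
          f"MD {np.median(fit.md[wm])*1e3:.3f}e-3")

mask = analysis_mask(fit.fa, threshold=0.2)
print(f"\nFA>=0.2 analysis mask: {mask.sum()} voxels "
      f"(covers {100*(mask & wm).sum()/wm.sum():.0f}% of the WM core). "
      "Noiseless recovery is exact; Rician noise biases FA slightly "
      "upward, which is why paired inference compares like with like.")
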