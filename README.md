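# coilbias

**Paired head-coil MRI bias estimation and voxelwise scaling-factor
harmonization, on synthetic phantom cohorts with known ground truth.**

Pooling MRI data acquired with different receive head coils — or swapping
coils mid-study — biases every standard quantitative analysis: the coils'
spatial sensitivity (gain) profiles alter image intensity, contrast and
SNR, which propagates into tissue segmentation ("volume" changes),
diffusion-tensor metrics, and resting-state connectivity. `coilbias` is a
testbed for this problem. It simulates within-subject paired acquisitions
under two parametric coil profiles — an *8-channel-like* coil (frontal-high
gain with a central drop) and a *32-channel-like* coil (homogeneous,
posterior-high) — runs registration-free analogues of the standard analysis
chains, quantifies the coil differences with nonparametric paired
inference, and estimates/validates voxelwise scaling factors that
harmonize one coil's images into the other's intensity space.

Everything downstream also accepts real NIfTI-1 volumes; the synthetic
cohort exists so that every stage is testable against known ground truth
without any data download.

## What is implemented

| Stage | Method |
|---|---|
| SNR mapping | Non-overlapping 16×16-voxel ROIs; SNR = mean(signal) / (√(2/(4−π)) · SD(noise)), the Rayleigh-SD correction for magnitude (Rician) data |
| VBM-lite | Polynomial bias-field correction, 3-class Gaussian-mixture EM segmentation (posteriors as partial volumes), Gaussian smoothing (σ = 3 mm ⇒ FWHM ≈ 7 mm) |
| DTI | Voxelwise log-linear OLS tensor fit; FA/MD with eigenvalue clamping; analysis mask at mean FA ≥ 0.2 |
| rs-fMRI | 6 mm FWHM smoothing, 0.01 Hz cosine-basis high-pass, two-stage dual regression against network + WM/CSF templates, per-network z-maps |
| Inference | Within-subject paired t-maps → TFCE (H=2, E=0.5, 26-connectivity, 100 adaptive steps) → sign-flip max-statistic permutation FWE (5000 permutations, α=0.05 by default; full enumeration when 2ⁿ ≤ n_perm), effect sizes and percent change |
| Harmonization | Age/sex-matched template/validation split; voxelwise mean(32CH)/mean(8CH) ratio, median-filtered (5 mm); multiply 8CH images into 32CH space; validate by re-running the paired inference |

The TFCE transform is computed with an incremental union-find over voxels
in descending order (exact, ~1 ms per 10⁴-voxel map), which makes
500-permutation max-TFCE nulls cheap enough to study type-I calibration
over hundreds of simulated cohorts.

## Worked example

```python
import numpy as np
from coilbias.synthetic import CohortConfig, make_cohort
from coilbias.pipeline import ExperimentConfig, run_experiment

cfg = ExperimentConfig(n_subjects=8, n_perm=200, seed=0)
bundle = run_experiment(cfg)
print(bundle["table"].to_string(index=False))
```

prints (gray/white matter comparison of a default cohort, where the two
coils differ only in gain and noise, followed by the post-harmonization
re-test):

```
      metric direction  n_sig_voxels  effect_size  pct_change  n_perm  config_hash  seed
          gm       pos             0          NaN         NaN     200 287fb7b9abb1     0
          gm       neg          1029      -1.1281     -7.4035     200 287fb7b9abb1     0
          wm       pos             0          NaN         NaN     200 287fb7b9abb1     0
          wm       neg             0          NaN         NaN     200 287fb7b9abb1     0
harmonize_t1      both             0          NaN         NaN     200 287fb7b9abb1     0
```

Read: even with *zero* injected contrast difference, the coil gain fields
alone shift the segmentation enough that apparent gray-matter volume
differs significantly between coils in 1029 voxels (a −7.4% apparent
change with paired Cohen's d ≈ −1.1) — while after voxelwise scaling-factor
harmonization the validation half of the cohort shows no significant
difference at all (`harmonize_t1` row). That is the bias-and-repair story
the package exists to demonstrate.

A thin CLI mirrors the library (`coilbias simulate | snr | vbm | dti |
rsfmri | stats | harmonize estimate/apply/validate | run`); see
`examples/` for one short script per capability.

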