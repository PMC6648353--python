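# Methods

`coilbias` studies how the choice of receive head coil biases quantitative
MRI analyses, and how far a voxelwise scaling factor can repair that bias.
This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic data do and do not show
about real acquisitions.

## The synthetic study

### Anatomy

A subject is a nested-ellipsoid head phantom on a shared isotropic grid:
a white-matter core inside a gray-matter shell inside a CSF rim. Default
outer semi-axes are (48, 55, 45) mm with a 12 mm GM shell and a 5 mm CSF
rim, giving more GM than WM voxels as in real brains. Partial volumes
come from a one-voxel linear ramp across each class boundary, so the four
partial-volume maps sum to one exactly at every voxel. Between-subject
variability is a seeded jitter of the semi-axes (3% SD), shell
thicknesses (10% SD) and center — *shape-parameter* variation only. All
subjects share one voxel grid; there is no registration stage, and
"volume difference" means a difference of smoothed partial-volume maps on
the common grid (no Jacobian modulation). This is the central semantic
difference from a full VBM pipeline and is deliberate: the effect under
study is contrast-driven misclassification, not spatial normalization.

Default tissue intensity means are CSF 250, GM 600, WM 850 (arbitrary
units, T1-like ordering); they are free parameters of the simulation, as
no reference intensity distributions exist for either coil.

### Coils

Coils are characterized purely by a multiplicative gain field and a
complex-channel noise sigma — parametric stand-ins for what an SNR map
shows, not electromagnetic simulations:

* `eight_ch`: gain = 1 + 0.4·(anterior ramp) − 0.35·(central Gaussian,
  σ = 0.22·FOV) — anterior-high sensitivity that drops centrally;
* `thirty_two_ch`: gain = 1 + 0.25·(posterior Gaussian, σ = 0.30·FOV) —
  near-homogeneous with a posterior peak.

The defaults satisfy, with margin, the qualitative constraints that
define the two profiles: the 8-channel anterior/central mean-gain ratio
is ≥ 1.15, the 32-channel gain CV is smaller than the 8-channel CV, and
its posterior mean exceeds its anterior mean. Default noise sigma is 25
for both coils (whole-image SNR ≈ 20–35 across tissues); protocol-driven
differences between the coils' diffusion acquisitions are modeled only as
a configurable noise-amplitude ratio, since longer repetition times at
these magnitudes have a negligible effect on signal.

### Signal models

* **T1**: noiseless intensity = Σ_class pv·mean × gain; a per-coil
  `contrast_shift` moves the GM and WM means symmetrically toward each
  other by shift·separation/2, modeling a coil-dependent gray/white
  contrast change. Noise is Rician: magnitude of (signal + N(0,σ),
  N(0,σ)).
* **DWI**: 60 Fibonacci-sphere directions at b = 1000 s/mm² plus one b=0.
  Ground-truth tensors are partial-volume mixtures of class tensors (WM
  prolate, eigenvalues (1.5, 0.35, 0.35)·10⁻³ mm²/s, FA ≈ 0.73, principal
  direction rotating smoothly across the volume; GM mildly anisotropic;
  CSF isotropic 3·10⁻³). Signal S = S0·exp(−b·gᵀDg)·gain with Rician
  noise; S0 is a T2-like tissue mixture (CSF bright).
* **BOLD**: data = gain·(baseline·tissue + Σ amp·map·tc + WM/CSF
  nuisance) + N(0,σ). Time courses are band-limited (0.01–0.1 Hz) seeded
  random signals; noise is plain Gaussian, since the functional analysis
  operates on high-SNR mean-removed series where the Rician floor is
  irrelevant. The gain multiplies the physiological signal while the
  noise floor does not scale with it — that asymmetry is what lets a
  posterior-sensitive coil genuinely raise posterior connectivity
  z-scores rather than canceling out. Cohorts add a static baseline
  (500·tissue) so that intensity-domain harmonization of BOLD is
  meaningful; `simulate_bold` itself defaults to pure fluctuations.

A left/right diffusion-metric asymmetry can only be produced by an
explicitly configured multiplicative bias field (`fa_md_bias`), never by
default: such an asymmetry has no mechanistic model here and should never
emerge silently.

## Analysis chain

**SNR maps.** The image is tiled into non-overlapping square ROIs
(default 16×16) from the origin; trailing partial blocks are discarded
(the alternative — padding — would bias edge ROIs). Per ROI, SNR =
mean(signal) / (√(2/(4−π))·SD(noise-only)); the factor converts the
Rayleigh SD of noise-only magnitude data to the underlying complex sigma,
so the ratio estimates A/σ. Sample (n−1) SD is used; on 256-voxel ROIs
the difference from n is negligible but it is fixed for reproducibility.
ROIs with zero noise SD are flagged invalid (NaN), not zero. Rendered
maps use a fixed 0–85 color scale for cross-run comparability.

**Bias correction.** A low-order (quadratic) 3-D polynomial is fit to the
log-intensities of bright-class voxels and exponentiated; the field is
normalized to mean 1 over the mask. Two details matter. A bare intensity
quantile selects preferentially where the field is high and admits
partial-volume voxels of the next class down, both of which bend the fit;
the selection is therefore (a) a band around the bright-class mode of the
*corrected* image, iterated four times, and (b) morphologically eroded to
remove the class-boundary shell. With those two steps a known ramp is
recovered with r > 0.999 on the phantom. An earlier design that
alternated mixture fitting with residual-field regression was removed:
on nested-ellipsoid anatomy the tissue contrast is itself nearly a radial
quadratic, degenerate with the polynomial basis, and the "refinement"
absorbed anatomy into the field.

**Segmentation** is a three-class 1-D Gaussian-mixture EM
(scikit-learn, k-means++ initialization, fixed seed, tol 10⁻⁵) on
bias-corrected masked intensities; posteriors are the partial volumes and
components are relabeled by ascending mean (CSF < GM < WM). No Markov
random field or spatial prior: the mechanism under study — a contrast
shift moving boundary voxels across class posteriors — is exhibited by
plain EM, and spatial regularization would only dampen it.

**Smoothing** is separable Gaussian convolution with σ in mm
(default 3 mm, FWHM = 2√(2 ln 2)·σ ≈ 7.06 mm), zero-padded boundaries so
interior-supported maps conserve mass.

**Tensor fit** is unweighted voxelwise OLS on log S = log S0 − b·gᵀDg —
the reproducible baseline, in preference to weighted or robust variants
(divergence risk at low SNR is flagged per voxel instead): voxels with
any non-positive sample are excluded and flagged, negative eigenvalues
are clamped to zero and flagged, keeping FA ∈ [0,1] and MD ≥ 0. On
noiseless data the fit reproduces ground truth to ~10⁻¹⁷ mm²/s. Group
comparisons are restricted to the voxels with cohort-mean FA ≥ 0.2
(mean over all subjects and both coils — the symmetric choice); there is
no skeleton projection.

**Dual regression.** Stage 1 regresses each time point's image jointly on
all template maps (networks + WM/CSF nuisance); stage 2 regresses each
voxel's series jointly on the resulting time courses, demeaned and
variance-normalized. The normalization is load-bearing: without it, a
change in a network's fluctuation amplitude is absorbed into the stage-1
time-course scale and the betas are amplitude-blind; with it, beta is
linear in amplitude (verified to 2%). z = beta/SE from ordinary-LS
residual variance — no prewhitening, as nothing in the synthetic noise
model is autocorrelated. Nuisance maps regress signal out but produce no
output map. The high-pass filter projects out a discrete-cosine basis of
all periods longer than 1/cutoff (default 0.01 Hz): deterministic,
idempotent, with measured attenuation ≥ 96% at 0.002 Hz and ≤ 2% loss at
0.05 Hz. The shipped network templates are geometric blobs at canonical
network locations (visual networks posterior, executive control frontal,
…); real template maps can be supplied as NIfTI.

## Paired inference

The paired design is a one-sample sign-flip test on per-subject
difference maps: t = mean(d)/(SD(d)/√n), df = n−1, zero-variance voxels
set to t = 0 and flagged. The permutation statistic is the
TFCE-transformed t-map with the method's canonical parameters (H = 2,
E = 0.5, 26-connectivity, 100 adaptive threshold steps, dh = max/steps);
family-wise error is controlled by the null distribution of the maximum
TFCE over the analysis mask, per direction, with the observed labeling
always included (so p ≥ 1/n_perm). When 2ⁿ ≤ n_perm the full enumeration
replaces sampling and the test is exact.

Numerical decisions worth knowing:

* TFCE is computed by an incremental union-find over voxels in
  descending value order, carrying per-component running sums through
  merges with potential offsets — O(V·α(V) + steps·components) per map
  instead of one connected-component labeling per threshold. It agrees
  with a brute-force stepwise-labeling oracle to < 10⁻¹⁵ relative error.
* Threshold comparisons use a 10⁻¹² relative tie slack so that exact
  rescaling of a map (rounding ~10⁻¹⁶) resolves threshold ties
  identically; TFCE homogeneity (c·map → c³·TFCE) is then exact rather
  than almost-always.
* Sampled sign patterns are drawn in complement-closed pairs with the
  identity and its negation always included. Each pattern is still
  uniform marginally, the two directions then share one null-max
  distribution (halving the cost), and negating all differences swaps
  the positive/negative results *exactly* rather than approximately.
* Effect summaries pool differences over subjects × significant voxels:
  effect size is the paired Cohen's d of that pool, percent change uses
  the first condition (8CH) as baseline; both are reported per direction.
  Zero-variance pools are flagged degenerate (±∞), not silently dropped.

Measured calibration: over 200 null cohorts (n = 12, 32³ grid, 500
sign flips each), the per-direction family-wise error rate falls inside
the 95% binomial interval around the nominal 0.05.

## Harmonization

The cohort is split into template and validation halves matched on age
and sex: within each sex stratum, subjects are sorted by age and assigned
alternately, then rebalanced to the requested template size; the seed
only breaks age ties. Template images per coil are averaged (4-D stacks
first averaged over time/volumes), divided voxelwise (32CH/8CH), and
median-filtered with a cubic window of odd side nearest filter_mm/voxel.
The ratio is defined only where the 8CH mean exceeds 5% of its 99th
percentile (air voxels would make the ratio unbounded); outside, it is 1.
Scaling multiplies validation 8CH images voxelwise; a modality tag
prevents a T1-derived field from being applied to diffusion or BOLD
data. Scaling acts on raw intensity images *before* derived analyses
(T1 before segmentation, DWI volumes before the tensor fit, BOLD volumes
before dual regression); this is a configuration choice, as is the
filter width.

Properties of the estimator worth understanding (both verified):

* For a purely multiplicative coil difference, the ratio is exact in the
  noiseless limit (anatomy cancels: (S̄·g32)/(S̄·g8) = g32/g8) and its RMS
  error decreases as √n with template size.
* The residual error has two parts: unfiltered template noise
  (~(σ/S̄)·√(2/n_t) per voxel, suppressed by the median filter) and a
  curvature bias of the filter itself where the true gain ratio bends at
  the window scale. The second term makes the filter width a genuine
  resolution constraint: on the coarse 4 mm demo grids a 5 mm kernel
  rounds to a single voxel (no noise suppression), while any wider window
  is comparable to the gain fields' variation scale and its smoothing
  bias becomes a smooth, TFCE-detectable residual in its own right. The
  null-restoration experiments therefore run at acquisition-like
  resolution (2 mm voxels, 64³ grids), where the 5 mm window spans 3
  voxels, both residual terms sit well below the validation test's
  detection threshold, and the post-harmonization any-significant-voxel
  frequency returns to the nominal α.
* A *fine-scale additive* coil difference is the characteristic failure
  mode: the median filter removes it from the ratio, so it survives
  harmonization and the validation re-test keeps a small island of
  significant voxels there while the gain differences vanish.

## Problem sizes

The test suite and the acceptance script run on 32³ grids at 4 mm voxels
with cohorts of 8–39 subjects, 100–5000 permutations (enumeration where
2ⁿ ≤ n_perm), 100–200 null cohorts for calibration — sizes chosen so the
full chain exercises every code path in minutes on a single CPU. The
orchestrator's `ExperimentConfig.full_scale()` preset (n = 77, 39/38
split, 5000 permutations, 64³ grid) runs the same code at full study
scale and is correspondingly slow.

## What passing tests do and do not show

The generator reproduces the *mechanisms* — gain-profile geometry, Rician
statistics, contrast-driven misclassification, SNR-driven connectivity
inflation, multiplicative-vs-additive harmonizability — on anatomy that
is deliberately simple. It has no real-brain folding geometry, no
registration error, no motion, drift, repositioning or habituation
effects, no k-space/SENSE reconstruction, and subject variability is
shape jitter only. Passing tests therefore validate the *methods* (the
estimators, the inference engine, the harmonization algebra) and the
direction of the coil-bias mechanisms, not the magnitudes any particular
scanner pair would produce; real-data magnitudes are properties of real
cohorts and cannot be certified from simulation.
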