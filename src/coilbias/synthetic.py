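"""Synthetic paired-coil, multi-modality MRI cohorts with known ground truth.

Every downstream stage of the pipeline (SNR mapping, tissue segmentation,
tensor fitting, dual regression, paired inference, harmonization) is
exercised on data produced here, so the generators are first-class, tested
code.  A subject is a nested-ellipsoid head phantom (CSF rim, gray-matter
shell, white-matter core) acquired twice: once through an "8-channel-like"
receive profile (anterior-high gain with a central drop) and once through a
"32-channel-like" profile (spatially homogeneous, posterior-high gain).
Both acquisitions of a subject share the identical phantom; only the coil
gain field, the noise realization, and any explicitly injected coil effect
(gray/white contrast shift, diffusion-metric bias field) differ.

Noise model: T1 and diffusion volumes carry Rician noise, i.e. the
magnitude of (signal + complex Gaussian); BOLD series carry plain Gaussian
noise, since the functional analysis operates on high-SNR mean-removed
series where the Rician floor is irrelevant.

Axis convention: axis 1 (``y``) of every grid is posterior -> anterior with
increasing index; "anterior third" means the top third of that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TissuePhantom",
    "CoilProfile",
    "DiffusionScheme",
    "TensorFieldTruth",
    "SubjectPair",
    "CohortConfig",
    "make_tissue_phantom",
    "make_coil_profile",
    "make_diffusion_scheme",
    "make_tensor_truth",
    "simulate_t1",
    "simulate_dwi",
    "simulate_bold",
    "make_cohort",
    "rician",
    "anterior_third",
    "central_third",
    "posterior_third",
    "bandlimited_timecourse",
    "DEFAULT_TISSUE_MEANS",
    "DEFAULT_S0_MEANS",
    "DEFAULT_DIFFUSIVITIES",
]

# T1-like arbitrary-unit class means: CSF < GM < WM.
DEFAULT_TISSUE_MEANS = {"csf": 250.0, "gm": 600.0, "wm": 850.0}
# b=0 (T2-weighted) signal per class: CSF bright.
DEFAULT_S0_MEANS = {"csf": 1000.0, "gm": 800.0, "wm": 700.0}
# Class diffusion tensor eigenvalues, mm^2/s.  WM is prolate (FA ~ 0.73 by
# construction, comfortably above the 0.4 floor the truth field guarantees),
# GM mildly anisotropic, CSF isotropic and fast.
DEFAULT_DIFFUSIVITIES = {
    "wm": (1.5e-3, 0.35e-3, 0.35e-3),
    "gm": (0.9e-3, 0.7e-3, 0.7e-3),
    "csf": (3.0e-3, 3.0e-3, 3.0e-3),
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TissuePhantom:
    """Three-tissue partial-volume head phantom on an isotropic grid.

    ``pv_gm + pv_wm + pv_csf + pv_background == 1`` at every voxel.
    """

    pv_gm: np.ndarray
    pv_wm: np.ndarray
    pv_csf: np.ndarray
    tissue_means: dict
    shape_params: dict
    voxel_mm: float
    deform_seed: int

    @property
    def pv_background(self) -> np.ndarray:
        return 1.0 - (self.pv_gm + self.pv_wm + self.pv_csf)

    @property
    def brain_mask(self) -> np.ndarray:
        """Voxels that are mostly head (any tissue class)."""
        return (self.pv_gm + self.pv_wm + self.pv_csf) > 0.5

    @property
    def grid_shape(self) -> tuple:
        return self.pv_gm.shape


@dataclass
class CoilProfile:
    """Parametric receive-coil signature: multiplicative gain + noise level.

    ``noise_sigma`` is the Gaussian sigma of each complex channel before
    magnitude reconstruction (so noise-only magnitude is Rayleigh).
    """

    kind: str  # "eight_ch" | "thirty_two_ch"
    gain: np.ndarray
    noise_sigma: float
    voxel_mm: float
    params: dict = field(default_factory=dict)


@dataclass
class DiffusionScheme:
    """Gradient table: b-values (s/mm^2) and unit direction vectors."""

    bvals: np.ndarray  # (N,)
    bvecs: np.ndarray  # (N, 3), unit rows (b=0 rows may be zero)

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    def validate(self) -> None:
        if np.any(self.bvals < 0):
            raise ValueError("negative b-value in scheme")
        if self.n_b0 < 1:
            raise ValueError("scheme needs at least one b=0 volume")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must have unit norm")


@dataclass
class TensorFieldTruth:
    """Ground-truth per-voxel diffusion tensor field (mm^2/s)."""

    d_tensor: np.ndarray  # (*grid, 3, 3) symmetric PSD
    principal_direction: np.ndarray  # (*grid, 3) unit vectors


@dataclass
class SubjectPair:
    """One subject: shared phantom + matched acquisitions under both coils."""

    subject_id: str
    phantom: TissuePhantom
    age: float
    sex: str
    t1_8ch: np.ndarray | None = None
    t1_32ch: np.ndarray | None = None
    dwi_8ch: np.ndarray | None = None
    dwi_32ch: np.ndarray | None = None
    bold_8ch: np.ndarray | None = None
    bold_32ch: np.ndarray | None = None
    truth: dict = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Study conditions for a paired-coil cohort.

    Defaults mirror the acquisition being emulated: 60-direction b=1000
    diffusion with one b=0, 200-volume TR=2.2 s BOLD, and coil gain shapes
    chosen so the 8-channel profile is frontal-high with a central drop and
    the 32-channel profile is homogeneous with a posterior peak.  Injected
    coil effects (``contrast_shift_*``, ``fa_md_bias``) default to zero: a
    default cohort differs between coils only through gain and noise.
    """

    grid_shape: tuple = (32, 32, 32)
    voxel_mm: float = 4.0
    modalities: tuple = ("t1",)
    noise_sigma_8ch: float = 25.0
    noise_sigma_32ch: float = 25.0
    dwi_noise_ratio_8ch: float = 1.0  # emulates protocol differences as noise scaling
    contrast_shift_8ch: float = 0.0
    contrast_shift_32ch: float = 0.0
    gain_params_8ch: dict = field(default_factory=dict)
    gain_params_32ch: dict = field(default_factory=dict)
    fa_md_bias: np.ndarray | None = None  # optional multiplicative tensor bias field
    n_bold_volumes: int = 200
    tr_s: float = 2.2
    bold_noise_sigma: float = 1.0
    bold_amplitudes: Sequence[float] | None = None
    bold_baseline: float = 500.0  # static mean image (needed for intensity scaling)
    age_range: tuple = (28.0, 76.0)
    female_fraction: float = 54.0 / 77.0


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

DEFAULT_SHAPE_PARAMS = {
    # outer (CSF envelope) semi-axes, mm; y (axis 1) is the long A-P axis
    "outer_radii_mm": (48.0, 55.0, 45.0),
    "gm_shell_mm": 12.0,  # gray-matter shell thickness
    "csf_rim_mm": 5.0,    # CSF rim thickness
    "radius_jitter": 0.03,    # per-axis fractional SD of the random perturbation
    "thickness_jitter": 0.10, # fractional SD on shell thicknesses
}


def _ellipsoid_rho(grid_shape, voxel_mm, radii_mm, center_mm):
    """Normalized elliptical radius: 1.0 on the ellipsoid surface."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * voxel_mm - c
        for n, c in zip(grid_shape, center_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    a, b, c = radii_mm
    return np.sqrt((xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2)


def make_tissue_phantom(
    grid_shape=(64, 64, 64),
    voxel_mm: float = 2.0,
    seed: int = 0,
    shape_params: dict | None = None,
    tissue_means: dict | None = None,
) -> TissuePhantom:
    """Build a nested-ellipsoid head phantom with anti-aliased boundaries.

    The head is a CSF rim around a gray-matter shell around a white-matter
    core.  Per-subject anatomy variation is a smooth random perturbation of
    the semi-axes and shell thicknesses (seeded, hence reproducible).
    Partial volumes arise from a linear one-voxel-wide ramp across each
    class boundary, so they always sum to one exactly.

    Raises ``ValueError`` if the grid cannot contain all three shells.
    """
    if any(n < 32 for n in grid_shape):
        raise ValueError("grid_shape must be at least 32 voxels per axis")
    sp = dict(DEFAULT_SHAPE_PARAMS)
    if shape_params:
        sp.update(shape_params)
    rng = np.random.default_rng(seed)

    base_radii = np.asarray(sp["outer_radii_mm"], dtype=float)
    fov_half = np.array([(n - 1) / 2.0 * voxel_mm for n in grid_shape])
    if np.any(base_radii > fov_half - voxel_mm):
        raise ValueError(
            f"grid {grid_shape} at {voxel_mm} mm cannot contain outer radii "
            f"{base_radii} mm")

    radii = base_radii * (1.0 + sp["radius_jitter"] * rng.standard_normal(3))
    # jitter never pushes the head outside the field of view
    radii = np.minimum(radii, fov_half - voxel_mm)
    gm_shell = sp["gm_shell_mm"] * (1.0 + sp["thickness_jitter"] * rng.standard_normal())
    csf_rim = sp["csf_rim_mm"] * (1.0 + sp["thickness_jitter"] * rng.standard_normal())
    gm_shell = max(gm_shell, 1.0)
    csf_rim = max(csf_rim, 1.0)
    center = 0.15 * voxel_mm * rng.standard_normal(3)

    rho = _ellipsoid_rho(grid_shape, voxel_mm, radii, center)
    r_mean = float(np.mean(radii))
    # class boundaries in normalized-radius units
    b_outer = 1.0
    b_gm = 1.0 - csf_rim / r_mean
    b_wm = b_gm - gm_shell / r_mean
    if b_wm <= 0.1:
        raise ValueError("shell thicknesses leave no room for a white-matter core")

    w = voxel_mm / r_mean  # one-voxel anti-aliasing width in rho units

    def inside(boundary):
        return np.clip((boundary - rho) / w + 0.5, 0.0, 1.0)

    in_wm = inside(b_wm)
    in_gm = inside(b_gm)
    in_head = inside(b_outer)
    pv_wm = in_wm
    pv_gm = in_gm - in_wm
    pv_csf = in_head - in_gm

    return TissuePhantom(
        pv_gm=pv_gm,
        pv_wm=pv_wm,
        pv_csf=pv_csf,
        tissue_means=dict(tissue_means or DEFAULT_TISSUE_MEANS),
        shape_params={
            "outer_radii_mm": tuple(radii),
            "gm_shell_mm": gm_shell,
            "csf_rim_mm": csf_rim,
            "center_mm": tuple(center),
        },
        voxel_mm=voxel_mm,
        deform_seed=seed,
    )


# ---------------------------------------------------------------------------
# coil profiles
# ---------------------------------------------------------------------------

DEFAULT_GAIN_PARAMS = {
    "eight_ch": {"baseline": 1.0, "a": 0.4, "b": 0.35},
    "thirty_two_ch": {"baseline": 1.0, "c": 0.25},
}


def make_coil_profile(
    kind: str,
    grid_shape=(64, 64, 64),
    voxel_mm: float = 2.0,
    params: dict | None = None,
    noise_sigma: float = 25.0,
    seed: int = 0,
) -> CoilProfile:
    """Parametric coil gain field.

    ``eight_ch``: baseline x (1 + a * anterior ramp - b * central Gaussian
    dip) — frontal-high sensitivity that drops in central/medial areas.
    ``thirty_two_ch``: baseline x (1 + c * posterior Gaussian) — nearly
    homogeneous with its peak in posterior cortex.  Defaults a=0.4, b=0.35,
    c=0.25 satisfy the qualitative constraints (anterior/central mean-gain
    ratio >= 1.15 for 8CH; 32CH gain CV below 8CH CV with posterior >=
    anterior mean).

    Raises ``ValueError`` for an unknown kind or if the parameters drive
    the gain non-positive anywhere.
    """
    if kind not in ("eight_ch", "thirty_two_ch"):
        raise ValueError(f"unknown coil kind {kind!r}")
    p = dict(DEFAULT_GAIN_PARAMS[kind])
    if params:
        p.update(params)

    axes = [np.arange(n) * voxel_mm for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    extent = [(n - 1) * voxel_mm for n in grid_shape]
    cx, cy, cz = [e / 2.0 for e in extent]

    if kind == "eight_ch":
        ramp = yy / extent[1]  # 0 posterior -> 1 anterior
        sig = 0.22 * extent[1]
        dip = np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2) + ((zz - cz) ** 2)) / (2 * sig**2))
        gain = p["baseline"] * (1.0 + p["a"] * ramp - p["b"] * dip)
    else:
        sig = 0.30 * extent[1]
        post = np.exp(-(((xx - cx) ** 2) + ((yy - 0.15 * extent[1]) ** 2) + ((zz - cz) ** 2)) / (2 * sig**2))
        gain = p["baseline"] * (1.0 + p["c"] * post)

    if np.any(gain <= 0):
        raise ValueError("coil parameters produce non-positive gain")
    return CoilProfile(kind=kind, gain=gain, noise_sigma=float(noise_sigma),
                       voxel_mm=voxel_mm, params=p)


def anterior_third(arr: np.ndarray) -> np.ndarray:
    """Slice of the anterior third along the A-P axis (axis 1, high index)."""
    n = arr.shape[1]
    return arr[:, 2 * n // 3:, :]


def central_third(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[1]
    return arr[:, n // 3: 2 * n // 3, :]


def posterior_third(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[1]
    return arr[:, : n // 3, :]


# ---------------------------------------------------------------------------
# noise + acquisitions
# ---------------------------------------------------------------------------

def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + N(0,sigma)) + i N(0,sigma).

    With ``signal == 0`` this is Rayleigh: mean sigma*sqrt(pi/2), SD
    sigma*sqrt((4-pi)/2).
    """
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    im = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(re, im)


def _shifted_means(means: dict, contrast_shift: float) -> dict:
    """Shrink the GM/WM mean separation by ``contrast_shift`` (fractional).

    Models a coil-dependent gray/white contrast change: GM and WM means
    move symmetrically toward each other by shift*separation/2 each.
    """
    out = dict(means)
    sep = means["wm"] - means["gm"]
    out["gm"] = means["gm"] + 0.5 * contrast_shift * sep
    out["wm"] = means["wm"] - 0.5 * contrast_shift * sep
    return out


def simulate_t1(
    phantom: TissuePhantom,
    coil: CoilProfile,
    contrast_shift: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """T1-like acquisition: gain-weighted tissue mixture + Rician noise.

    Noiseless intensity at a voxel is sum_class pv * mean_class (with the
    GM/WM separation reduced by ``contrast_shift``) times the coil gain.
    """
    if contrast_shift < 0:
        raise ValueError("contrast_shift must be >= 0")
    m = _shifted_means(phantom.tissue_means, contrast_shift)
    signal = (
        phantom.pv_csf * m["csf"] + phantom.pv_gm * m["gm"] + phantom.pv_wm * m["wm"]
    ) * coil.gain
    rng = np.random.default_rng(seed)
    return rician(signal, coil.noise_sigma, rng)


# ---------------------------------------------------------------------------
# diffusion
# ---------------------------------------------------------------------------

def make_diffusion_scheme(n_directions: int = 60, bval: float = 1000.0,
                          n_b0: int = 1) -> DiffusionScheme:
    """Deterministic gradient table: Fibonacci-sphere directions + b=0 rows.

    60 non-collinear directions at b=1000 s/mm^2 with one b=0 by default.
    """
    i = np.arange(n_directions)
    ga = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n_directions
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = ga * i
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, bval)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    scheme = DiffusionScheme(bvals=bvals, bvecs=bvecs)
    scheme.validate()
    return scheme


def _tensor_from_eigs(eigs, direction):
    """Symmetric tensor with largest eigenvalue along ``direction``."""
    l1, l2, l3 = eigs
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # complete an orthonormal frame
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(d, a)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    return l1 * np.outer(d, d) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)


def make_tensor_truth(phantom: TissuePhantom,
                      diffusivities: dict | None = None) -> TensorFieldTruth:
    """Ground-truth tensor field from the phantom's tissue composition.

    WM carries a prolate tensor whose principal direction varies smoothly
    across the volume (a gently rotating field mimicking tract curvature);
    GM is mildly anisotropic, CSF isotropic.  The voxel tensor is the
    partial-volume-weighted sum of class tensors, so WM-dominated voxels
    have truth FA >= 0.4 and pure-CSF voxels are isotropic.
    """
    dv = dict(DEFAULT_DIFFUSIVITIES)
    if diffusivities:
        dv.update(diffusivities)
    shape = phantom.grid_shape
    axes = [np.linspace(-1, 1, n) for n in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    # smoothly varying unit field: blends x and z with position
    dir_field = np.stack([np.cos(0.8 * yy), 0.2 * np.ones_like(yy), np.sin(0.8 * yy)],
                         axis=-1)
    dir_field /= np.linalg.norm(dir_field, axis=-1, keepdims=True)

    flat_dir = dir_field.reshape(-1, 3)
    # per-voxel orthonormal frame (vectorized): e1 = principal direction
    a = np.where(np.abs(flat_dir[:, :1]) < 0.9,
                 np.array([[1.0, 0.0, 0.0]]), np.array([[0.0, 1.0, 0.0]]))
    e2 = np.cross(flat_dir, a)
    e2 /= np.linalg.norm(e2, axis=1, keepdims=True)
    e3 = np.cross(flat_dir, e2)

    def aniso_tensor(eigs):
        l1, l2, l3 = eigs
        return (l1 * flat_dir[:, :, None] * flat_dir[:, None, :]
                + l2 * e2[:, :, None] * e2[:, None, :]
                + l3 * e3[:, :, None] * e3[:, None, :])

    csf_t = np.diag(dv["csf"]).astype(float)
    d_flat = phantom.pv_wm.ravel()[:, None, None] * aniso_tensor(dv["wm"])
    d_flat += phantom.pv_gm.ravel()[:, None, None] * aniso_tensor(dv["gm"])
    d_flat += phantom.pv_csf.ravel()[:, None, None] * csf_t
    return TensorFieldTruth(d_tensor=d_flat.reshape(shape + (3, 3)),
                            principal_direction=dir_field)


def simulate_dwi(
    phantom: TissuePhantom,
    tensor_truth: TensorFieldTruth,
    scheme: DiffusionScheme,
    coil: CoilProfile,
    seed: int = 0,
    noise_sigma: float | None = None,
) -> np.ndarray:
    """Diffusion acquisition: S = S0 exp(-b g'Dg) * gain + Rician noise.

    S0 comes from the tissue composition (b=0 / T2-like class means).
    Returns a 4-D stack (*grid, n_volumes).  ``noise_sigma`` defaults to
    the coil's sigma; pass explicitly to model protocol-driven noise
    differences between coils.
    """
    scheme.validate()
    if tensor_truth.d_tensor.shape[:3] != phantom.grid_shape:
        raise ValueError("tensor field and phantom grids differ")
    s0 = (
        phantom.pv_csf * DEFAULT_S0_MEANS["csf"]
        + phantom.pv_gm * DEFAULT_S0_MEANS["gm"]
        + phantom.pv_wm * DEFAULT_S0_MEANS["wm"]
    )
    d_flat = tensor_truth.d_tensor.reshape(-1, 3, 3)
    # quadratic form g'Dg as a (N,6)@(6,V) matmul over unique elements
    d6 = np.stack([d_flat[:, 0, 0], d_flat[:, 1, 1], d_flat[:, 2, 2],
                   d_flat[:, 0, 1], d_flat[:, 0, 2], d_flat[:, 1, 2]])
    g = scheme.bvecs
    w = np.stack([g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
                  2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2],
                  2 * g[:, 1] * g[:, 2]], axis=1)
    quad = w @ d6  # (N, V)
    atten = np.exp(-scheme.bvals[:, None] * quad)  # (N, V)
    signal = (s0.ravel()[None, :] * atten) * coil.gain.ravel()[None, :]
    sigma = coil.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(seed)
    noisy = rician(signal, sigma, rng)
    return np.moveaxis(noisy.reshape((scheme.n_volumes,) + phantom.grid_shape), 0, -1)


# ---------------------------------------------------------------------------
# BOLD
# ---------------------------------------------------------------------------

def bandlimited_timecourse(n_volumes: int, tr_s: float,
                           rng: np.random.Generator,
                           band_hz=(0.01, 0.1)) -> np.ndarray:
    """Zero-mean, unit-SD random signal with power confined to ``band_hz``."""
    freqs = np.fft.rfftfreq(n_volumes, d=tr_s)
    spec = np.zeros(len(freqs), dtype=complex)
    sel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not np.any(sel):  # very short series: keep the lowest nonzero bin
        sel = np.zeros_like(freqs, dtype=bool)
        sel[min(1, len(freqs) - 1)] = True
    spec[sel] = rng.standard_normal(sel.sum()) + 1j * rng.standard_normal(sel.sum())
    tc = np.fft.irfft(spec, n=n_volumes)
    tc -= tc.mean()
    sd = tc.std()
    return tc / sd if sd > 0 else tc


def simulate_bold(
    phantom: TissuePhantom,
    templates,  # NetworkTemplateSet (rsfmri) or sequence of maps
    amplitudes: Sequence[float],
    coil: CoilProfile,
    n_volumes: int = 200,
    tr_s: float = 2.2,
    seed: int = 0,
    noise_sigma: float = 1.0,
    nuisance_amplitude: float = 1.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Resting-state series: network maps x band-limited time courses.

    data(t) = gain * [ baseline*tissue + sum_k amp_k map_k tc_k(t) +
    WM/CSF nuisance ] + Gaussian noise.  The coil gain multiplies the
    physiological signal so a coil with higher local gain yields higher
    local temporal SNR — the mechanism by which a posterior-sensitive coil
    inflates posterior network connectivity.  ``baseline`` adds a static
    tissue-weighted mean image (zero by default: the default series is
    pure fluctuation).  Defaults: 200 volumes at TR 2.2 s.
    """
    if n_volumes < 20:
        raise ValueError("n_volumes must be >= 20")
    net_maps = getattr(templates, "network_maps", templates)
    net_maps = [np.asarray(m) for m in net_maps]
    if len(net_maps) != len(amplitudes):
        raise ValueError("one amplitude per template is required")
    for m in net_maps:
        if m.shape != phantom.grid_shape:
            raise ValueError("template map shape differs from phantom grid")
    rng = np.random.default_rng(seed)
    data = np.zeros(phantom.grid_shape + (n_volumes,))
    if baseline != 0.0:
        tissue = phantom.pv_gm + phantom.pv_wm + phantom.pv_csf
        data += baseline * tissue[..., None]
    for amp, m in zip(amplitudes, net_maps):
        tc = bandlimited_timecourse(n_volumes, tr_s, rng)
        data += amp * m[..., None] * tc[None, None, None, :]
    # WM and CSF nuisance fluctuations
    for nmap in (phantom.pv_wm, phantom.pv_csf):
        tc = bandlimited_timecourse(n_volumes, tr_s, rng)
        data += nuisance_amplitude * nmap[..., None] * tc[None, None, None, :]
    data *= coil.gain[..., None]
    if noise_sigma > 0:
        data += rng.normal(0.0, noise_sigma, size=data.shape)
    return data


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(n_subjects: int, config: CohortConfig | None = None,
                seed: int = 0) -> list[SubjectPair]:
    """Generate a paired-coil cohort with randomized demographics.

    Each subject's 8CH and 32CH acquisitions derive from one shared
    phantom; injected coil effects from the config are recorded in each
    subject's ``truth`` dict.  Fully deterministic under a fixed seed.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    demo_rng = np.random.default_rng(root.spawn(1)[0])
    subj_seeds = root.spawn(n_subjects)

    coil8 = make_coil_profile("eight_ch", cfg.grid_shape, cfg.voxel_mm,
                              cfg.gain_params_8ch, cfg.noise_sigma_8ch)
    coil32 = make_coil_profile("thirty_two_ch", cfg.grid_shape, cfg.voxel_mm,
                               cfg.gain_params_32ch, cfg.noise_sigma_32ch)

    ages = demo_rng.uniform(*cfg.age_range, size=n_subjects)
    sexes = np.where(demo_rng.random(n_subjects) < cfg.female_fraction, "F", "M")

    scheme = make_diffusion_scheme() if "dwi" in cfg.modalities else None
    from .rsfmri import make_network_templates  # local import: avoids cycle

    cohort: list[SubjectPair] = []
    for i in range(n_subjects):
        ss = subj_seeds[i]
        sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]
        phantom = make_tissue_phantom(cfg.grid_shape, cfg.voxel_mm,
                                      seed=sub_seeds[0])
        pair = SubjectPair(
            subject_id=f"sub-{i + 1:03d}",
            phantom=phantom,
            age=float(ages[i]),
            sex=str(sexes[i]),
            truth={
                "contrast_shift_8ch": cfg.contrast_shift_8ch,
                "contrast_shift_32ch": cfg.contrast_shift_32ch,
                "gain_8ch": coil8.gain,
                "gain_32ch": coil32.gain,
            },
        )
        if "t1" in cfg.modalities:
            pair.t1_8ch = simulate_t1(phantom, coil8, cfg.contrast_shift_8ch,
                                      seed=sub_seeds[1])
            pair.t1_32ch = simulate_t1(phantom, coil32, cfg.contrast_shift_32ch,
                                       seed=sub_seeds[2])
        if "dwi" in cfg.modalities:
            truth = make_tensor_truth(phantom)
            if cfg.fa_md_bias is not None:
                truth = TensorFieldTruth(
                    d_tensor=truth.d_tensor * cfg.fa_md_bias[..., None, None],
                    principal_direction=truth.principal_direction,
                )
                pair.truth["fa_md_bias"] = cfg.fa_md_bias
            pair.truth["tensor"] = truth
            pair.dwi_8ch = simulate_dwi(
                phantom, truth, scheme, coil8, seed=sub_seeds[3],
                noise_sigma=cfg.noise_sigma_8ch * cfg.dwi_noise_ratio_8ch)
            pair.dwi_32ch = simulate_dwi(phantom, truth, scheme, coil32,
                                         seed=sub_seeds[4])
        if "bold" in cfg.modalities:
            templates = make_network_templates(cfg.grid_shape, cfg.voxel_mm,
                                               phantom=phantom)
            amps = (cfg.bold_amplitudes
                    if cfg.bold_amplitudes is not None
                    else [1.0] * len(templates.network_maps))
            pair.truth["bold_amplitudes"] = list(amps)
            pair.bold_8ch = simulate_bold(
                phantom, templates, amps, coil8, cfg.n_bold_volumes, cfg.tr_s,
                seed=sub_seeds[5], noise_sigma=cfg.bold_noise_sigma,
                baseline=cfg.bold_baseline)
            pair.bold_32ch = simulate_bold(
                phantom, templates, amps, coil32, cfg.n_bold_volumes, cfg.tr_s,
                seed=sub_seeds[6], noise_sigma=cfg.bold_noise_sigma,
                baseline=cfg.bold_baseline)
        cohort.append(pair)
    return cohort
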