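"""Diffusion-tensor estimation and scalar metrics.

Ordinary least squares on the log-signal model log S = log S0 - b g'Dg,
solved voxelwise in one pass.  Negative eigenvalues (a low-SNR artifact of
the unconstrained fit) are clamped to zero before FA/MD are computed, and
such voxels are flagged.  Voxelwise group comparison is restricted to an
analysis mask of mean FA >= 0.2 (no tract skeletonization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import DiffusionScheme

__all__ = ["TensorFit", "design_matrix", "fit_tensor", "fa_of_tensor",
           "md_of_tensor", "tensor_from_elements", "analysis_mask"]

# order of the 6 unique tensor elements
TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class TensorFit:
    """Voxelwise tensor fit with derived scalar maps."""

    d_elements: np.ndarray  # (*grid, 6) in TENSOR_ELEMENTS order, mm^2/s
    s0: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    fit_ok: np.ndarray      # False where any input signal <= 0
    clamped: np.ndarray     # True where eigenvalues were clamped to >= 0

    def tensors(self) -> np.ndarray:
        """Full (*grid, 3, 3) symmetric tensor array."""
        return tensor_from_elements(self.d_elements)


def design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """(N, 7) design for the log-linear model: [1, -b*quad terms]."""
    b = scheme.bvals
    g = scheme.bvecs
    cols = np.stack([
        np.ones_like(b),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ], axis=1)
    return cols


def tensor_from_elements(d_elements: np.ndarray) -> np.ndarray:
    """Assemble symmetric 3x3 tensors from the 6 unique elements."""
    e = np.asarray(d_elements)
    t = np.empty(e.shape[:-1] + (3, 3))
    t[..., 0, 0] = e[..., 0]
    t[..., 1, 1] = e[..., 1]
    t[..., 2, 2] = e[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = e[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = e[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = e[..., 5]
    return t


def fa_of_tensor(eigenvalues) -> float:
    """Fractional anisotropy of three non-negative eigenvalues (0 if all zero)."""
    lam = np.asarray(eigenvalues, dtype=float)
    denom = np.sqrt(np.sum(lam**2))
    if denom == 0:
        return 0.0
    l1, l2, l3 = lam
    num = np.sqrt(0.5) * np.sqrt((l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2)
    return float(num / denom)


def md_of_tensor(eigenvalues) -> float:
    """Mean diffusivity: (l1 + l2 + l3) / 3."""
    lam = np.asarray(eigenvalues, dtype=float)
    return float(lam.sum() / 3.0)


def fit_tensor(dwi_stack: np.ndarray, scheme: DiffusionScheme) -> TensorFit:
    """Voxelwise OLS tensor fit of a 4-D stack (*grid, n_volumes).

    Requires >= 7 volumes including at least one b=0, and a non-singular
    gradient design (non-collinear directions).  Voxels with any
    non-positive signal are excluded from the fit and flagged.
    """
    scheme.validate()
    dwi_stack = np.asarray(dwi_stack, dtype=float)
    if dwi_stack.shape[-1] != scheme.n_volumes:
        raise ValueError("stack volume count does not match the scheme")
    if scheme.n_volumes < 7:
        raise ValueError("need at least 7 volumes to fit a tensor")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("singular design: gradient directions are collinear")

    grid = dwi_stack.shape[:-1]
    flat = dwi_stack.reshape(-1, scheme.n_volumes)
    fit_ok = np.all(flat > 0, axis=1)
    logs = np.zeros_like(flat)
    logs[fit_ok] = np.log(flat[fit_ok])
    coef = np.zeros((flat.shape[0], 7))
    if fit_ok.any():
        sol, *_ = np.linalg.lstsq(X, logs[fit_ok].T, rcond=None)
        coef[fit_ok] = sol.T

    s0 = np.exp(coef[:, 0]) * fit_ok
    d_elem = coef[:, 1:]
    # dxy/dxz/dyz columns already carry the 1/2 via the design's factor 2
    tens = tensor_from_elements(d_elem)
    lam = np.linalg.eigvalsh(tens)  # ascending
    clamped = np.any(lam < 0, axis=-1) & fit_ok
    lam = np.clip(lam, 0.0, None)

    md = lam.mean(axis=-1)
    sq = np.sum(lam**2, axis=-1)
    dev = np.sum((lam - md[..., None]) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev / sq)
    fa = np.where(sq > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0) * fit_ok
    md = md * fit_ok

    return TensorFit(
        d_elements=d_elem.reshape(grid + (6,)),
        s0=s0.reshape(grid),
        fa=fa.reshape(grid),
        md=md.reshape(grid),
        fit_ok=fit_ok.reshape(grid),
        clamped=clamped.reshape(grid),
    )


def analysis_mask(mean_fa: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Binary analysis mask: voxels whose cohort-mean FA >= ``threshold``.

    ``mean_fa`` is the voxelwise mean FA over all subjects and both coils
    on the common grid.
    """
    mean_fa = np.asarray(mean_fa, dtype=float)
    return np.isfinite(mean_fa) & (mean_fa >= threshold)
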