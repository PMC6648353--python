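"""Resting-state preprocessing and dual-regression connectivity.

The chain: volume-wise spatial smoothing (FWHM given in mm), high-pass
temporal filtering by projection onto a discrete-cosine drift basis
(removes frequencies below the cutoff together with the series mean), and
two-stage dual regression against a set of network template maps plus WM
and CSF nuisance maps:

  stage 1 — at each time point, regress the image on all spatial maps
            jointly, yielding one time course per map;
  stage 2 — at each voxel, regress the series on all time courses jointly,
            yielding one beta map per map; z = beta / SE(beta) from the
            ordinary-least-squares residual variance.

Only the network (non-nuisance) maps produce output z-maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .vbm import sigma_from_fwhm, smooth_gaussian

__all__ = ["NetworkTemplateSet", "ConnectivityMaps", "make_network_templates",
           "highpass", "smooth_fwhm", "dual_regression"]

# canonical resting-state networks of interest (posterior-to-frontal mix)
DEFAULT_NETWORK_NAMES = (
    "medial_visual", "lateral_visual", "auditory_salience", "sensorimotor",
    "default_mode", "executive_control", "dorsal_stream_left",
    "dorsal_stream_right",
)


@dataclass
class NetworkTemplateSet:
    """Spatial regressor set: network maps + WM/CSF nuisance maps."""

    network_maps: list
    nuisance_maps: list
    names: tuple
    nuisance_names: tuple = ("wm", "csf")

    def all_maps(self) -> list:
        return list(self.network_maps) + list(self.nuisance_maps)

    def validate(self, grid_shape) -> None:
        for m in self.all_maps():
            if np.asarray(m).shape != tuple(grid_shape):
                raise ValueError("template map is not on the analysis grid")
            if not np.all(np.isfinite(m)):
                raise ValueError("template map contains non-finite values")
        flat = np.stack([np.asarray(m).ravel() for m in self.all_maps()])
        if np.linalg.matrix_rank(flat) < flat.shape[0]:
            raise ValueError("template + nuisance maps are rank-deficient")


def _blob(grid_shape, voxel_mm, center_frac, sigma_mm):
    axes = [np.arange(n) * voxel_mm for n in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    extent = [(n - 1) * voxel_mm for n in grid_shape]
    cx, cy, cz = [f * e for f, e in zip(center_frac, extent)]
    return np.exp(-(((xx - cx) ** 2) + ((yy - cy) ** 2) + ((zz - cz) ** 2))
                  / (2.0 * sigma_mm**2))

# blob centres as fractions of the grid extent; y (axis 1) is posterior->anterior
_NETWORK_CENTERS = {
    "medial_visual": (0.50, 0.18, 0.45),
    "lateral_visual": (0.70, 0.22, 0.50),
    "auditory_salience": (0.28, 0.50, 0.45),
    "sensorimotor": (0.50, 0.52, 0.75),
    "default_mode": (0.50, 0.62, 0.55),
    "executive_control": (0.50, 0.78, 0.60),
    "dorsal_stream_left": (0.30, 0.35, 0.65),
    "dorsal_stream_right": (0.70, 0.35, 0.65),
}


def make_network_templates(grid_shape, voxel_mm: float = 2.0,
                           phantom=None, sigma_frac: float = 0.10
                           ) -> NetworkTemplateSet:
    """Synthetic network template set: one smooth blob per canonical network.

    Geometric stand-ins for standard resting-state network maps (visual
    networks posterior, executive control frontal, etc.), plus WM and CSF
    nuisance maps taken from the phantom's partial volumes when a phantom
    is given (otherwise concentric shells).
    """
    extent = min((n - 1) * voxel_mm for n in grid_shape)
    sigma_mm = sigma_frac * extent
    maps = [_blob(grid_shape, voxel_mm, _NETWORK_CENTERS[name], sigma_mm)
            for name in DEFAULT_NETWORK_NAMES]
    if phantom is not None:
        nuis = [phantom.pv_wm.astype(float), phantom.pv_csf.astype(float)]
    else:
        inner = _blob(grid_shape, voxel_mm, (0.5, 0.5, 0.5), 0.18 * extent)
        outer = _blob(grid_shape, voxel_mm, (0.5, 0.5, 0.5), 0.35 * extent)
        nuis = [inner, np.clip(outer - inner, 0.0, None)]
    ts = NetworkTemplateSet(network_maps=maps, nuisance_maps=nuis,
                            names=DEFAULT_NETWORK_NAMES)
    ts.validate(grid_shape)
    return ts


@dataclass
class ConnectivityMaps:
    """Per-network subject connectivity: betas, z-scores, stage-1 time courses."""

    beta_maps: dict
    z_maps: dict
    timecourses: np.ndarray  # (n_volumes, n_maps) incl. nuisance columns
    names: tuple
    nuisance_names: tuple = ("wm", "csf")


def highpass(series_4d: np.ndarray, cutoff_hz: float = 0.01,
             tr_s: float = 2.2) -> np.ndarray:
    """Remove slow drifts below ``cutoff_hz`` (and the mean) from each voxel.

    Implemented as regression onto a discrete-cosine basis spanning all
    periods longer than 1/cutoff; deterministic and exactly idempotent.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    series_4d = np.asarray(series_4d, dtype=float)
    n = series_4d.shape[-1]
    # DCT-II regressor k has frequency k / (2 N TR)
    k_max = int(np.floor(2.0 * n * tr_s * cutoff_hz))
    t = np.arange(n)
    basis = [np.ones(n)]
    for k in range(1, k_max + 1):
        basis.append(np.cos(np.pi * k * (t + 0.5) / n))
    X = np.stack(basis, axis=1)
    flat = series_4d.reshape(-1, n).T  # (n, V)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    return resid.T.reshape(series_4d.shape)


def smooth_fwhm(series_4d: np.ndarray, fwhm_mm: float = 6.0,
                voxel_mm: float = 2.0) -> np.ndarray:
    """Volume-wise spatial smoothing with the kernel given as FWHM in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.asarray(series_4d, dtype=float).copy()
    return smooth_gaussian(np.asarray(series_4d, dtype=float),
                           sigma_from_fwhm(fwhm_mm), voxel_mm)


def dual_regression(series_4d: np.ndarray,
                    templates: NetworkTemplateSet) -> ConnectivityMaps:
    """Two-stage dual regression of one subject's series on template maps.

    Returns beta and z maps for the network templates only; the WM/CSF
    nuisance maps participate in both regressions but produce no output
    map.  Raises on rank-deficient designs, naming the offending maps.
    """
    series_4d = np.asarray(series_4d, dtype=float)
    grid = series_4d.shape[:-1]
    n_t = series_4d.shape[-1]
    templates.validate(grid)
    all_maps = templates.all_maps()
    all_names = tuple(templates.names) + tuple(templates.nuisance_names)
    if n_t <= len(all_maps):
        raise ValueError("series shorter than the number of spatial regressors")

    S = np.stack([np.asarray(m).ravel() for m in all_maps], axis=1)  # (V, K)
    Y = series_4d.reshape(-1, n_t)  # (V, T)

    # stage 1: spatial regression -> one time course per map
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError(f"rank-deficient spatial design: {all_names}")
    tc, *_ = np.linalg.lstsq(S, Y, rcond=None)  # (K, T)
    tc = tc.T  # (T, K)

    # stage 2: temporal regression -> one beta per map per voxel.  Time
    # courses are demeaned and variance-normalized (unit SD) so that betas
    # carry the data's amplitude units: doubling a network's fluctuation
    # amplitude doubles its beta instead of being absorbed into the
    # stage-1 time-course scale.
    X = tc - tc.mean(axis=0, keepdims=True)
    sd = X.std(axis=0)
    if np.any(sd == 0) or np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient temporal design: {all_names}")
    X = X / sd
    Yd = (Y - Y.mean(axis=1, keepdims=True)).T  # (T, V)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Yd  # (K, V)
    resid = Yd - X @ beta
    dof = n_t - X.shape[1] - 1  # -1 for the removed mean
    sigma2 = np.sum(resid**2, axis=0) / dof  # (V,)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        z = np.where(se > 0, beta / se, 0.0)

    beta_maps, z_maps = {}, {}
    for ki, name in enumerate(templates.names):
        beta_maps[name] = beta[ki].reshape(grid)
        z_maps[name] = z[ki].reshape(grid)
    return ConnectivityMaps(beta_maps=beta_maps, z_maps=z_maps,
                            timecourses=tc, names=tuple(templates.names))
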