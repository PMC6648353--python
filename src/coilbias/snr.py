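"""ROI-wise SNR maps from a signal image and a noise-only image.

The estimator follows the classic two-acquisition scheme for magnitude MR
data: the image is tiled into non-overlapping square ROIs (default 16x16
voxels), and per ROI

    SNR = mean(signal) / ( sqrt(2/(4-pi)) * SD(noise) )

where SD is the sample (n-1) standard deviation of the noise-only image in
the same ROI.  Because noise-only magnitude data are Rayleigh distributed,
their SD equals sigma*sqrt((4-pi)/2) of the underlying complex Gaussian;
the sqrt(2/(4-pi)) factor converts the measured Rayleigh SD back to sigma,
so the ratio estimates A/sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RICIAN_CORRECTION", "SNRMap", "roi_partition", "snr_of_roi",
           "snr_map", "render_snr_map"]

#: sqrt(2/(4-pi)) — converts Rayleigh SD to the complex-channel sigma.
RICIAN_CORRECTION = float(np.sqrt(2.0 / (4.0 - np.pi)))


@dataclass
class SNRMap:
    """ROI grid of SNR estimates for one slice orientation."""

    values: np.ndarray          # (rows, cols) SNR per ROI; NaN = invalid ROI
    roi_size: int
    plane: str                  # axial | coronal | sagittal
    region_means: dict          # anterior / central / posterior ROI means

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


def roi_partition(image_2d: np.ndarray, roi_size: int = 16) -> np.ndarray:
    """Tile a 2-D image into non-overlapping roi_size x roi_size blocks.

    Blocks are tiled from the image origin; trailing partial blocks are
    discarded.  Returns an array of shape (rows, cols, roi, roi).
    """
    image_2d = np.asarray(image_2d)
    if roi_size < 2:
        raise ValueError("roi_size must be >= 2")
    if image_2d.ndim != 2:
        raise ValueError("expected a 2-D image")
    nr, nc = image_2d.shape[0] // roi_size, image_2d.shape[1] // roi_size
    if nr == 0 or nc == 0:
        raise ValueError(
            f"image {image_2d.shape} smaller than one {roi_size}x{roi_size} block")
    trimmed = image_2d[: nr * roi_size, : nc * roi_size]
    return trimmed.reshape(nr, roi_size, nc, roi_size).swapaxes(1, 2)


def snr_of_roi(signal_block: np.ndarray, noise_block: np.ndarray) -> float:
    """Rician-corrected SNR of one ROI; NaN if the noise block is constant."""
    signal_block = np.asarray(signal_block, dtype=float)
    noise_block = np.asarray(noise_block, dtype=float)
    if signal_block.shape != noise_block.shape:
        raise ValueError("signal and noise blocks must have the same shape")
    sd = noise_block.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        return float("nan")
    return float(signal_block.mean() / (RICIAN_CORRECTION * sd))


def snr_map(signal_image: np.ndarray, noise_image: np.ndarray,
            roi_size: int = 16, plane: str = "axial") -> SNRMap:
    """ROI-wise SNR over a slice; summarizes anterior/central/posterior.

    Both images must share a shape; axis 0 of the slice is taken as the
    posterior -> anterior direction for the regional summary.
    """
    signal_image = np.asarray(signal_image, dtype=float)
    noise_image = np.asarray(noise_image, dtype=float)
    if signal_image.shape != noise_image.shape:
        raise ValueError("signal and noise images must have the same shape")
    sig_blocks = roi_partition(signal_image, roi_size)
    noi_blocks = roi_partition(noise_image, roi_size)
    means = sig_blocks.mean(axis=(2, 3))
    sds = noi_blocks.std(axis=(2, 3), ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = means / (RICIAN_CORRECTION * sds)
    values[~(sds > 0)] = np.nan

    n = values.shape[0]
    thirds = {
        "posterior": values[: n // 3],
        "central": values[n // 3: 2 * n // 3],
        "anterior": values[2 * n // 3:],
    }
    region_means = {k: float(np.nanmean(v)) if v.size else float("nan")
                    for k, v in thirds.items()}
    return SNRMap(values=values, roi_size=roi_size, plane=plane,
                  region_means=region_means)


def render_snr_map(snr: SNRMap, path, vmax: float = 85.0) -> None:
    """Write a color-coded PNG of the ROI SNR grid (fixed 0–``vmax`` scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(snr.values.T, origin="lower", cmap="jet", vmin=0.0, vmax=vmax)
    ax.set_title(f"SNR ({snr.plane}, ROI {snr.roi_size})")
    fig.colorbar(im, ax=ax, label="SNR")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
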