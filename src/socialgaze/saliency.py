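"""Bottom-up saliency maps: a simplified center-surround reference model,
plus loading of maps computed by any external model.

The downstream analyses treat saliency as a pluggable input. The reference
implementation follows the classic feature-channel recipe — intensity, two
color-opponency channels and oriented contrast, each as multi-scale
center-surround differences, max-normalized per channel and averaged with
equal weights — which is sufficient for controlled synthetic stimuli and
method validation. It makes no claim to benchmark-grade accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SaliencyMap",
    "compute_reference_saliency",
    "load_saliency_map",
    "save_saliency_map",
    "map_summary",
]


@dataclass
class SaliencyMap:
    values: np.ndarray  # (H, W), float in [0, 1]
    scene_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("saliency map must be a 2-D matrix")
        self.values = v


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi > lo:
        return (v - lo) / (hi - lo)
    return np.zeros_like(v)


def _center_surround(channel: np.ndarray, n_scales: int) -> np.ndarray:
    """Across-scale sum of |center - surround| band-pass responses.

    Center/surround are Gaussian blurs at dyadic scale pairs (sigma, 4*sigma)
    with sigma = 2**s for s = 1..n_scales; each scale's response is
    max-normalized before summation so no single scale dominates.
    """
    acc = np.zeros_like(channel)
    for s in range(1, n_scales + 1):
        sig = 2.0**s
        c = ndimage.gaussian_filter(channel, sig, mode="nearest")
        su = ndimage.gaussian_filter(channel, 4.0 * sig, mode="nearest")
        resp = np.abs(c - su)
        m = resp.max()
        if m > 0:
            acc += resp / m
    return acc


def _orientation_channels(intensity: np.ndarray, n_orient: int = 4) -> list[np.ndarray]:
    """Oriented contrast via second-derivative-of-Gaussian filters."""
    out = []
    gx = ndimage.gaussian_filter(intensity, 2.0, order=(0, 2), mode="nearest")
    gy = ndimage.gaussian_filter(intensity, 2.0, order=(2, 0), mode="nearest")
    gxy = ndimage.gaussian_filter(intensity, 2.0, order=(1, 1), mode="nearest")
    for k in range(n_orient):
        theta = np.pi * k / n_orient
        # directional second derivative along theta
        c, s = np.cos(theta), np.sin(theta)
        out.append(np.abs(c * c * gx + s * s * gy + 2 * c * s * gxy))
    return out


def compute_reference_saliency(
    image: np.ndarray,
    *,
    n_scales: int = 4,
    center_bias_strength: float = 0.0,
    scene_id: str = "",
) -> SaliencyMap:
    """Center-surround conspicuity over intensity, color opponency and
    orientation, min-max normalized to [0, 1].

    Parameters
    ----------
    image : ndarray
        RGB image (H, W, 3) with values in [0, 1] or [0, 255]; a grayscale
        (H, W) input is accepted with a warning (color channels become zero).
    n_scales : int
        Number of dyadic center-surround scales.
    center_bias_strength : float
        If > 0, the conspicuity is multiplied by
        ``exp(-strength * d^2 / (2 * sigma_cb^2))`` with ``sigma_cb`` a
        quarter of the image diagonal. Off by default: the patch analysis
        models the central bias as an explicit predictor.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        warnings.warn("grayscale input: color channels computed as zero")
        img = np.stack([img, img, img], axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image (H, W, 3)")
    h, w = img.shape[:2]
    if min(h, w) < 64:
        raise ValueError(f"image too small for multi-scale analysis: {img.shape}")
    if img.max() > 1.5:
        img = img / 255.0
    if center_bias_strength < 0:
        raise ValueError("center_bias_strength must be >= 0")

    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    intensity = img.mean(axis=-1)
    rg = r - g
    by = b - (r + g) / 2.0

    chan_intensity = _center_surround(intensity, n_scales)
    chan_color = _minmax(_center_surround(rg, n_scales)) + _minmax(
        _center_surround(by, n_scales)
    )
    orient = _orientation_channels(intensity)
    chan_orient = np.sum([_minmax(_center_surround(o, n_scales)) for o in orient], axis=0)

    sal = (
        _minmax(chan_intensity) + _minmax(chan_color) + _minmax(chan_orient)
    ) / 3.0

    if center_bias_strength > 0:
        yy, xx = np.mgrid[0:h, 0:w]
        d2 = (xx - (w - 1) / 2.0) ** 2 + (yy - (h - 1) / 2.0) ** 2
        sigma_cb = np.hypot(h, w) / 4.0
        sal = sal * np.exp(-center_bias_strength * d2 / (2.0 * sigma_cb**2))

    return SaliencyMap(_minmax(sal), scene_id)


def load_saliency_map(path, scene_id: str = "", expected_shape: tuple[int, int] | None = None) -> SaliencyMap:
    """Load a single-channel float matrix (TIFF or .npy) as a saliency map.

    Values are min-max rescaled to [0, 1] unless already in range with
    min 0 and max 1 (idempotent on already-normalized maps).
    """
    path = Path(path)
    if path.suffix.lower() == ".npy":
        v = np.load(path)
    else:
        import tifffile

        v = tifffile.imread(path)
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel matrix, got shape {v.shape}")
    if expected_shape is not None and v.shape != tuple(expected_shape):
        raise ValueError(f"{path}: shape {v.shape} does not match scene {expected_shape}")
    if not (v.min() == 0.0 and v.max() == 1.0):
        v = _minmax(v)
    return SaliencyMap(v, scene_id)


def save_saliency_map(m: SaliencyMap, path) -> None:
    """Write as 32-bit float single-channel TIFF (or .npy by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".npy":
        np.save(path, m.values.astype(np.float32))
    else:
        import tifffile

        tifffile.imwrite(path, m.values.astype(np.float32))


def map_summary(m: SaliencyMap) -> tuple[float, float]:
    """Mean and sample SD (n-1) of all pixel values."""
    v = m.values
    return float(v.mean()), float(v.std(ddof=1))
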