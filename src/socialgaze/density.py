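"""Duration-weighted, Gaussian-smoothed fixation density maps.

Each fixation deposits its duration (ms) at its rounded pixel position; the
impulse image is smoothed with an isotropic 2-D Gaussian (default sigma = 36
px, about 1 degree of visual angle, so +/- 1 SD covers the fovea) and
min-max normalized to [0, 1].

Because the pre-smoothing image is a sum of impulses, the convolution is
evaluated by splatting a truncated separable kernel patch per fixation,
which is algebraically identical to convolving the accumulator with the
same truncated kernel under zero padding but orders of magnitude faster for
the ~30 fixations of a 10-s trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .events import Fixation
from .geometry import ViewingGeometry

__all__ = ["DensityMap", "build_density_map", "accumulate_durations"]

#: kernel support in units of sigma (per side)
TRUNCATE = 4.0


@dataclass
class DensityMap:
    values: np.ndarray  # (H, W), float, in [0, 1]
    participant_id: str
    scene_id: str
    n_fixations: int
    total_duration_ms: float


def _kernel_1d(sigma: float) -> np.ndarray:
    r = int(TRUNCATE * sigma + 0.5)
    u = np.arange(-r, r + 1, dtype=float)
    k = np.exp(-0.5 * (u / sigma) ** 2)
    return k / k.sum()


def accumulate_durations(fixations, shape: tuple[int, int]) -> tuple[np.ndarray, int, float]:
    """Duration impulses at rounded fixation pixels; off-image fixations dropped."""
    h, w = shape
    acc = np.zeros((h, w), dtype=float)
    n_used = 0
    total = 0.0
    for f in fixations:
        col = int(round(f.x))
        row = int(round(f.y))
        if not (0 <= col < w and 0 <= row < h):
            warnings.warn(f"fixation at ({f.x:.1f}, {f.y:.1f}) is off-image; dropped")
            continue
        acc[row, col] += f.duration
        n_used += 1
        total += f.duration
    return acc, n_used, total


def build_density_map(
    fixations: list[Fixation],
    geometry: ViewingGeometry,
    *,
    sigma_px: float = 36.0,
    participant_id: str = "",
    scene_id: str = "",
) -> DensityMap:
    """Build the normalized fixation density map for one trial.

    Zero-fixation trials yield an all-zero map (flagged by ``n_fixations``).
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    h, w = geometry.image_height_px, geometry.image_width_px
    out = np.zeros((h, w), dtype=float)
    k = _kernel_1d(sigma_px)
    r = len(k) // 2
    n_used = 0
    total = 0.0
    for f in fixations:
        col = int(round(f.x))
        row = int(round(f.y))
        if not (0 <= col < w and 0 <= row < h):
            warnings.warn(f"fixation at ({f.x:.1f}, {f.y:.1f}) is off-image; dropped")
            continue
        r0, r1 = max(0, row - r), min(h, row + r + 1)
        c0, c1 = max(0, col - r), min(w, col + r + 1)
        ky = k[r0 - row + r : r1 - row + r]
        kx = k[c0 - col + r : c1 - col + r]
        out[r0:r1, c0:c1] += f.duration * np.outer(ky, kx)
        n_used += 1
        total += f.duration

    peak = out.max()
    if peak > 0:
        mn = out.min()
        out = (out - mn) / (peak - mn)
    elif n_used:  # degenerate: all mass identical, map constant
        out[:] = 0.0
    return DensityMap(out, participant_id, scene_id, n_used, total)
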