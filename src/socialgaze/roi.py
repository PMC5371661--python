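"""Region-of-interest scoring for social scenes.

Four ROIs partition each social scene: heads, bodies (heads excluded), and —
over the remaining pixels — areas of lower and higher physical saliency,
split at the 8th saliency decile (80th percentile) of the non-social pixels.
Two scores are computed per ROI: relative mean saliency (ROI mean / scene
mean) and relative area-normalized fixation density (share of density mass
divided by the ROI's share of scene area, so a uniform density scores 1
everywhere).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .density import DensityMap
from .saliency import SaliencyMap

__all__ = ["ROI_NAMES", "RoiSet", "RoiScore", "build_roi_set", "roi_relative_saliency", "roi_norm_fixation_density"]

ROI_NAMES = ("head", "body", "lower", "higher")


@dataclass
class RoiSet:
    head_mask: np.ndarray
    body_mask: np.ndarray
    lower_sal_mask: np.ndarray
    higher_sal_mask: np.ndarray
    scene_id: str = ""

    def mask(self, roi: str) -> np.ndarray:
        return {
            "head": self.head_mask,
            "body": self.body_mask,
            "lower": self.lower_sal_mask,
            "higher": self.higher_sal_mask,
        }[roi]

    def area_fraction(self, roi: str) -> float:
        return float(self.mask(roi).mean())

    def label_at(self, row: int, col: int) -> str | None:
        """ROI label of a pixel, or None if out of bounds."""
        h, w = self.head_mask.shape
        if not (0 <= row < h and 0 <= col < w):
            return None
        for name in ROI_NAMES:
            if self.mask(name)[row, col]:
                return name
        return None  # unreachable for a valid partition


@dataclass(frozen=True)
class RoiScore:
    roi: str
    rel_saliency: float | None = None
    rel_norm_density: float | None = None


def build_roi_set(
    head_mask: np.ndarray,
    body_mask: np.ndarray,
    saliency: SaliencyMap,
    *,
    decile: float = 0.8,
    quantile_method: str = "linear",
) -> RoiSet:
    """Partition a scene into head / body / lower- / higher-saliency ROIs.

    Head pixels are removed from the body mask. Among the remaining
    (non-social) pixels, saliency values <= the ``decile`` quantile go to
    the lower-saliency ROI, the rest to the higher-saliency ROI.
    """
    head = np.asarray(head_mask, dtype=bool)
    body = np.asarray(body_mask, dtype=bool) & ~head
    if head.shape != saliency.values.shape or body.shape != saliency.values.shape:
        raise ValueError("mask shape does not match saliency map")
    social = head | body
    nonsocial = ~social
    if not nonsocial.any():
        raise ValueError("social ROIs cover the entire scene")
    vals = saliency.values[nonsocial]
    thresh = float(np.quantile(vals, decile, method=quantile_method))
    lower = nonsocial & (saliency.values <= thresh)
    higher = nonsocial & ~lower
    if not higher.any():
        warnings.warn("degenerate saliency: higher-saliency ROI is empty")
    return RoiSet(head, body, lower, higher, saliency.scene_id)


def roi_relative_saliency(roi_set: RoiSet, saliency: SaliencyMap) -> list[RoiScore]:
    """Mean saliency per ROI divided by the scene-wide mean saliency."""
    scene_mean = float(saliency.values.mean())
    scores = []
    for name in ROI_NAMES:
        m = roi_set.mask(name)
        if not m.any():
            warnings.warn(f"empty ROI {name!r}: relative saliency undefined")
            scores.append(RoiScore(name, rel_saliency=None))
            continue
        rel = float(saliency.values[m].mean()) / scene_mean if scene_mean > 0 else np.nan
        scores.append(RoiScore(name, rel_saliency=rel))
    return scores


def roi_norm_fixation_density(roi_set: RoiSet, density: DensityMap) -> list[RoiScore]:
    """Share of fixation-density mass per ROI, normalized by ROI area fraction."""
    total = float(density.values.sum())
    if total <= 0:
        raise ValueError("zero total fixation density")
    scores = []
    for name in ROI_NAMES:
        m = roi_set.mask(name)
        if not m.any():
            warnings.warn(f"empty ROI {name!r}: normalized density undefined")
            scores.append(RoiScore(name, rel_norm_density=None))
            continue
        proportion = float(density.values[m].sum()) / total
        scores.append(RoiScore(name, rel_norm_density=proportion / roi_set.area_fraction(name)))
    return scores
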