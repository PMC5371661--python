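"""Early-fixation time course: the first five fixations per trial.

Two analyses: (i) relative saliency inside a 2-degree-diameter foveal
window around each of the first five fixated locations (window mean /
scene mean), averaged per participant by fixation rank and scene category;
(ii) for social scenes, area-normalized ROI hit frequencies per fixation
rank. Trials whose drift-correction baseline was replaced are excluded —
their starting position is unreliable, which biases exactly these early
fixations. A pooled "6+" rank bin is kept for plotting parity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .events import Fixation, TrialEvents
from .roi import ROI_NAMES, RoiSet
from .saliency import SaliencyMap

__all__ = [
    "fixation_window_saliency",
    "trial_saliency_rows",
    "trial_roi_hits",
    "summarize_ranked_saliency",
    "summarize_roi_frequencies",
    "ranked_saliency_table",
    "ranked_roi_frequencies",
    "WINDOW_DIAMETER_PX",
]

#: 2 degrees of visual angle at the reference kernel scale (2 x 36 px)
WINDOW_DIAMETER_PX = 72.0

RANKS = ("1", "2", "3", "4", "5", "6+")


def fixation_window_saliency(
    fixation: Fixation,
    saliency: SaliencyMap,
    *,
    diameter_px: float = WINDOW_DIAMETER_PX,
) -> float | None:
    """Mean saliency in a circular foveal window, relative to the scene mean.

    Pixels whose centers lie within ``diameter_px / 2`` of the fixation point
    and inside the image contribute. Returns None when the window is fully
    off-image.
    """
    v = saliency.values
    h, w = v.shape
    rad = diameter_px / 2.0
    r0 = max(0, int(np.floor(fixation.y - rad)))
    r1 = min(h, int(np.ceil(fixation.y + rad)) + 1)
    c0 = max(0, int(np.floor(fixation.x - rad)))
    c1 = min(w, int(np.ceil(fixation.x + rad)) + 1)
    if r0 >= r1 or c0 >= c1:
        return None
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    d2 = (rows[:, None] - fixation.y) ** 2 + (cols[None, :] - fixation.x) ** 2
    inside = d2 <= rad**2
    if not inside.any():
        return None
    scene_mean = float(v.mean())
    if scene_mean <= 0:
        return np.nan
    return float(v[r0:r1, c0:c1][inside].mean()) / scene_mean


def _rank_of(i: int) -> str:
    return RANKS[i] if i < 5 else "6+"


def trial_saliency_rows(
    trial: TrialEvents,
    saliency: SaliencyMap,
    category: str,
    *,
    diameter_px: float = WINDOW_DIAMETER_PX,
) -> list[dict]:
    """Per-fixation relative window saliency for one (valid, unreplaced) trial."""
    rows = []
    for i, f in enumerate(trial.fixations):
        val = fixation_window_saliency(f, saliency, diameter_px=diameter_px)
        if val is None:
            warnings.warn(
                f"fixation rank {i + 1} off-image in trial "
                f"({trial.participant_id}, {trial.scene_id}); skipped"
            )
            continue
        rows.append(
            {
                "participant_id": trial.participant_id,
                "category": category,
                "rank": _rank_of(i),
                "rel_window_saliency": val,
            }
        )
    return rows


def trial_roi_hits(trial: TrialEvents, roi_set: RoiSet) -> list[dict]:
    """ROI label per in-image fixation of one social trial."""
    hits = []
    for i, f in enumerate(trial.fixations):
        label = roi_set.label_at(int(round(f.y)), int(round(f.x)))
        if label is None:
            continue
        hits.append(
            {
                "participant_id": trial.participant_id,
                "scene_id": trial.scene_id,
                "rank": _rank_of(i),
                "roi": label,
            }
        )
    return hits


def summarize_ranked_saliency(rows: pd.DataFrame) -> pd.DataFrame:
    """Participant x category x rank means of relative window saliency."""
    return rows.groupby(["participant_id", "category", "rank"], as_index=False)[
        "rel_window_saliency"
    ].mean()


def summarize_roi_frequencies(
    hits: pd.DataFrame,
    area_fractions: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Area-normalized ROI frequencies from per-fixation hit records.

    Per participant and rank, the relative frequency of each ROI
    (hits / all in-image hits) is divided by the mean area fraction of
    that ROI across exactly the scenes represented in that frequency.
    """
    rows = []
    for (pid, rank), grp in hits.groupby(["participant_id", "rank"]):
        n_any = len(grp)
        scenes = grp["scene_id"].unique()
        for roi in ROI_NAMES:
            rel = float((grp["roi"] == roi).sum()) / n_any
            mean_area = float(np.mean([area_fractions[s][roi] for s in scenes]))
            rows.append(
                {
                    "participant_id": pid,
                    "rank": rank,
                    "roi": roi,
                    "rel_freq": rel,
                    "norm_freq": rel / mean_area if mean_area > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def ranked_saliency_table(
    trials: list[TrialEvents],
    saliency_maps: dict[str, SaliencyMap],
    categories: dict[str, str],
    *,
    diameter_px: float = WINDOW_DIAMETER_PX,
) -> pd.DataFrame:
    """Participant x rank x category means of relative window saliency.

    Baseline-replaced and invalid trials are excluded (their starting
    position is unreliable). Returns a long DataFrame (participant_id,
    category, rank, rel_window_saliency).
    """
    rows: list[dict] = []
    for tr in trials:
        if not tr.valid or tr.baseline_replaced:
            continue
        rows.extend(
            trial_saliency_rows(
                tr, saliency_maps[tr.scene_id], categories[tr.scene_id], diameter_px=diameter_px
            )
        )
    return summarize_ranked_saliency(pd.DataFrame(rows))


def ranked_roi_frequencies(
    trials: list[TrialEvents],
    roi_sets: dict[str, RoiSet],
) -> pd.DataFrame:
    """Area-normalized ROI hit frequencies per participant and fixation rank.

    Social trials only; the ROI of a fixation is the label of its (rounded)
    pixel, off-image fixations are excluded from numerator and denominator.
    Returns a long DataFrame (participant_id, rank, roi, rel_freq,
    norm_freq).
    """
    hits: list[dict] = []
    for tr in trials:
        if not tr.valid or tr.baseline_replaced or tr.scene_id not in roi_sets:
            continue
        hits.extend(trial_roi_hits(tr, roi_sets[tr.scene_id]))
    if not hits:
        raise ValueError("no in-image fixations on social scenes")
    areas = {
        sid: {roi: rs.area_fraction(roi) for roi in ROI_NAMES} for sid, rs in roi_sets.items()
    }
    return summarize_roi_frequencies(pd.DataFrame(hits), areas)
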