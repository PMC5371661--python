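"""Saliency vs. fixation-density comparison metrics: D_KL, AUC, Pearson r.

Both maps are rescaled to sum to 1 (after epsilon regularization).
D_KL(F || S) measures how badly the saliency distribution S predicts the
fixation distribution F; AUC treats saliency values as classifier scores for
the above-mean-density binarization of the fixation map (rank-based
Mann-Whitney area, midranks for ties); r is the pixelwise Pearson
correlation. Per-participant category means feed the paired tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .density import DensityMap
from .saliency import SaliencyMap

__all__ = [
    "ComparisonResult",
    "compare_maps",
    "auc_from_scores",
    "aggregate_by_category",
]


@dataclass(frozen=True)
class ComparisonResult:
    d_kl: float
    auc: float
    r: float
    participant_id: str = ""
    scene_id: str = ""
    constant_saliency: bool = False


def _sum_normalize(v: np.ndarray, epsilon: float) -> np.ndarray:
    v = v.astype(float, copy=False) + epsilon
    return v / v.sum()


def auc_from_scores(scores: np.ndarray, labels: np.ndarray, *, ranks: np.ndarray | None = None) -> float:
    """Mann-Whitney AUC of ``scores`` predicting boolean ``labels``.

    Ties in scores are handled by midranks. ``ranks`` may supply precomputed
    ``scipy.stats.rankdata(scores)`` when the same score map is scored
    against many label maps. Returns 0.5 when either class is empty or the
    scores are constant.
    """
    labels = np.asarray(labels, dtype=bool).ravel()
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        return 0.5
    if ranks is None:
        scores = np.asarray(scores).ravel()
        if scores.max() == scores.min():
            return 0.5
        ranks = rankdata(scores)
    else:
        ranks = np.asarray(ranks).ravel()
        if ranks.max() == ranks.min():
            return 0.5
    rank_sum = float(ranks[labels].sum())
    u = rank_sum - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def compare_maps(
    saliency: SaliencyMap,
    density: DensityMap,
    *,
    epsilon: float = 1e-12,
    log_base: float | None = None,
    saliency_ranks: np.ndarray | None = None,
) -> ComparisonResult:
    """Compute D_KL(F || S), AUC and Pearson r for one trial.

    Parameters
    ----------
    epsilon : float
        Added to every cell of both maps before sum-normalization, avoiding
        log(0); results are stable over many orders of magnitude.
    log_base : float, optional
        Base of the KL logarithm; natural log (nats) when None.
    saliency_ranks : ndarray, optional
        Precomputed ``rankdata`` of the flattened saliency values, reusable
        across the many trials sharing one scene.
    """
    s = saliency.values
    f = density.values
    if s.shape != f.shape:
        raise ValueError(f"shape mismatch: saliency {s.shape} vs density {f.shape}")
    if density.n_fixations < 1 or f.max() <= 0:
        raise ValueError("density map has no fixations")

    fn = _sum_normalize(f.ravel(), epsilon)
    sn = _sum_normalize(s.ravel(), epsilon)

    d_kl = float(np.sum(fn * np.log(fn / sn)))
    if log_base is not None:
        d_kl /= np.log(log_base)
    d_kl = max(d_kl, 0.0)

    labels = f.ravel() > f.mean()
    constant_saliency = s.max() == s.min()
    if constant_saliency:
        warnings.warn("constant saliency map: auc = 0.5, r = 0 by convention")
        auc, r = 0.5, 0.0
    else:
        auc = auc_from_scores(s.ravel(), labels, ranks=saliency_ranks)
        r = float(np.corrcoef(fn, sn)[0, 1])

    return ComparisonResult(
        d_kl=d_kl,
        auc=auc,
        r=r,
        participant_id=density.participant_id,
        scene_id=density.scene_id,
        constant_saliency=constant_saliency,
    )


def aggregate_by_category(
    results: list[ComparisonResult],
    valid: dict[tuple[str, str], bool],
    categories: dict[str, str],
) -> pd.DataFrame:
    """Per-participant means of each metric, separately per scene category.

    Parameters
    ----------
    results : list of ComparisonResult
    valid : mapping (participant_id, scene_id) -> bool
        Trial validity (blink rule); invalid trials are excluded.
    categories : mapping scene_id -> category label

    Returns
    -------
    DataFrame with columns participant_id, category, d_kl, auc, r.
    """
    rows = []
    for res in results:
        if not valid.get((res.participant_id, res.scene_id), True):
            continue
        rows.append(
            {
                "participant_id": res.participant_id,
                "category": categories[res.scene_id],
                "d_kl": res.d_kl,
                "auc": res.auc,
                "r": res.r,
            }
        )
    if not rows:
        raise ValueError("no valid trials to aggregate")
    df = pd.DataFrame(rows)
    agg = df.groupby(["participant_id", "category"], as_index=False)[["d_kl", "auc", "r"]].mean()
    n_cat = len(set(categories.values()))
    counts = agg.groupby("participant_id").size()
    for pid, c in counts.items():
        if c < n_cat:
            warnings.warn(f"participant {pid} has no valid trials in some category; excluded")
    keep = counts[counts == n_cat].index
    return agg[agg["participant_id"].isin(keep)].reset_index(drop=True)
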