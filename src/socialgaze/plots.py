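"""Figure helpers: time-course line plots and decile-bin summaries.

Static matplotlib exports mirroring the analyses' standard presentation:
mean +/- SEM of relative window saliency by fixation rank and scene
category, area-normalized ROI fixation frequency by rank, and mean
relative fixation density per predictor decile bin.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .roi import ROI_NAMES
from .timecourse import RANKS

__all__ = ["plot_timecourse", "plot_decile_bins"]


def _mean_sem(groups):
    m = groups.mean()
    sem = groups.apply(lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0)
    return m, sem


def plot_timecourse(
    saliency_table: pd.DataFrame,
    roi_table: pd.DataFrame,
    path,
) -> None:
    """Two panels: rank x category window saliency; rank x ROI frequency."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    for cat in sorted(saliency_table["category"].unique()):
        sub = saliency_table[saliency_table["category"] == cat]
        g = sub.groupby("rank")["rel_window_saliency"]
        m, s = _mean_sem(g)
        m = m.reindex(list(RANKS)).dropna()
        s = s.reindex(m.index)
        ax1.errorbar(m.index, m.values, yerr=s.values, marker="o", capsize=3, label=cat)
    ax1.set_xlabel("fixation number")
    ax1.set_ylabel("relative window saliency")
    ax1.legend()

    for roi in ROI_NAMES:
        sub = roi_table[roi_table["roi"] == roi]
        g = sub.groupby("rank")["norm_freq"]
        m, s = _mean_sem(g)
        m = m.reindex(list(RANKS)).dropna()
        s = s.reindex(m.index)
        ax2.errorbar(m.index, m.values, yerr=s.values, marker="o", capsize=3, label=roi)
    ax2.set_xlabel("fixation number")
    ax2.set_ylabel("area-normalized fixation frequency")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_decile_bins(decile_summaries: dict[str, pd.DataFrame], path) -> None:
    """One panel per predictor: mean relative fixation density per bin."""
    n = len(decile_summaries)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.5), squeeze=False)
    for ax, (pred, table) in zip(axes[0], decile_summaries.items()):
        x = np.arange(len(table))
        ax.errorbar(x, table["mean"], yerr=table["sem"], marker="o", capsize=3)
        if (table["bin"] == "0").any():
            ax.axvline(0.5, linestyle="--", color="gray", linewidth=0.8)
        ax.set_xticks(x, table["bin"], rotation=0, fontsize=8)
        ax.set_title(pred, fontsize=10)
        ax.set_xlabel("bin")
    axes[0][0].set_ylabel("mean relative fixation density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
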