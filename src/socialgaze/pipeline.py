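"""End-to-end orchestration: from trials to the conclusion-bearing tables.

The runner streams scene by scene — generating (or loading) the scene's
saliency map and ROI masks, then iterating that scene's trials — so the
full cohort never holds more than one full-resolution map set in memory.
Downstream aggregation produces: per-trial saliency/density comparison
metrics with paired tests per participant, ROI saliency and gaze scores
with repeated-measures ANOVAs, the early-fixation time course, and the
scene-patch mixed-model ladder with likelihood-ratio comparisons and
decile summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import stats_rm
from .density import build_density_map
from .events import TrialEvents
from .geometry import ViewingGeometry, default_geometry
from .metrics import aggregate_by_category, compare_maps
from .patches import (
    compare_models,
    decile_bin_summary,
    fit_mixed_model,
    patch_response,
    scene_patch_features,
    standardize_predictors,
)
from .roi import ROI_NAMES, build_roi_set, roi_norm_fixation_density, roi_relative_saliency
from .simulate import (
    CohortConfig,
    GazeModelParams,
    SceneSampler,
    generate_scene,
    scene_specs_for_cohort,
    simulate_fixation_sequence,
)
from .timecourse import (
    summarize_ranked_saliency,
    summarize_roi_frequencies,
    trial_roi_hits,
    trial_saliency_rows,
)

__all__ = ["CohortResults", "run_synthetic_cohort", "analyze_trials"]

#: incremental model-comparison ladder (smaller, larger)
LRT_LADDER = [("0", "1a"), ("1a", "2"), ("2", "3a"), ("3a", "4"), ("4", "5a"), ("5a", "6")]


@dataclass
class CohortResults:
    trial_metrics: pd.DataFrame
    metrics_by_participant: pd.DataFrame
    paired_tests: pd.DataFrame
    roi_scene_saliency: pd.DataFrame
    roi_participant_density: pd.DataFrame
    roi_anovas: pd.DataFrame
    timecourse_saliency: pd.DataFrame
    timecourse_roi: pd.DataFrame
    timecourse_anovas: pd.DataFrame
    model_fits: dict
    model_table: pd.DataFrame
    lrt_table: pd.DataFrame
    decile_summaries: dict[str, pd.DataFrame]
    fixation_stats: pd.DataFrame
    patch_table: pd.DataFrame = field(repr=False, default=None)


def run_synthetic_cohort(
    config: CohortConfig,
    params: GazeModelParams | None = None,
    *,
    geometry: ViewingGeometry | None = None,
    sigma_px: float = 36.0,
    models: tuple[str, ...] = ("0", "1a", "1b", "1c", "1d", "2", "3a", "3b", "4", "5a", "5b", "6"),
    keep_patch_table: bool = False,
) -> CohortResults:
    """Simulate the default cohort at fixation level and analyze it fully.

    Fixation-level simulation bypasses event detection and drift correction
    (all trials valid, no baseline replacement), exercising every
    statistical stage at the study's scale. Sample-level simulation and the
    event-detection chain are exercised separately by their own modules.
    """
    params = params or GazeModelParams()
    geometry = geometry or default_geometry()
    specs = scene_specs_for_cohort(config)

    metric_results = []
    roi_sal_rows = []
    roi_density_rows = []
    sal_rank_rows: list[dict] = []
    roi_hit_rows: list[dict] = []
    patch_frames = []
    fix_count_rows = []
    categories: dict[str, str] = {}
    area_fractions: dict[str, dict[str, float]] = {}

    for s_idx, spec in enumerate(specs):
        scene = generate_scene(spec, (config.seed, 11, s_idx), geometry=geometry)
        categories[spec.scene_id] = spec.category
        sal = scene.saliency
        ranks = rankdata(sal.values.ravel())
        sampler = SceneSampler(scene, geometry)

        roi_set = None
        scene_features = None
        if spec.category == "social":
            roi_set = build_roi_set(scene.head_mask, scene.body_mask, sal)
            area_fractions[spec.scene_id] = {r: roi_set.area_fraction(r) for r in ROI_NAMES}
            for sc in roi_relative_saliency(roi_set, sal):
                roi_sal_rows.append(
                    {"scene_id": spec.scene_id, "roi": sc.roi, "rel_saliency": sc.rel_saliency}
                )
            scene_features = scene_patch_features(sal, roi_set)

        for p_idx in range(config.n_participants):
            pid = f"p{p_idx:03d}"
            rng = np.random.default_rng((config.seed % 2**31, 23, p_idx, s_idx))
            fixations = simulate_fixation_sequence(
                scene, params, rng, sampler=sampler, geometry=geometry,
                trial_duration_ms=config.trial_duration_ms,
            )
            trial = TrialEvents(pid, spec.scene_id, fixations=fixations, valid=True)
            fix_count_rows.append(
                {
                    "participant_id": pid,
                    "scene_id": spec.scene_id,
                    "category": spec.category,
                    "n_fixations": len(fixations),
                    "mean_duration_ms": float(np.mean([f.duration for f in fixations]))
                    if fixations
                    else np.nan,
                }
            )
            if not fixations:
                warnings.warn(f"trial ({pid}, {spec.scene_id}) produced no fixations")
                continue
            dens = build_density_map(
                fixations, geometry, sigma_px=sigma_px, participant_id=pid, scene_id=spec.scene_id
            )
            metric_results.append(compare_maps(sal, dens, saliency_ranks=ranks))
            sal_rank_rows.extend(trial_saliency_rows(trial, sal, spec.category))
            if roi_set is not None:
                for sc in roi_norm_fixation_density(roi_set, dens):
                    roi_density_rows.append(
                        {
                            "participant_id": pid,
                            "scene_id": spec.scene_id,
                            "roi": sc.roi,
                            "rel_norm_density": sc.rel_norm_density,
                        }
                    )
                roi_hit_rows.extend(trial_roi_hits(trial, roi_set))
                pf = scene_features.copy()
                pf.insert(0, "participant_id", pid)
                pf.insert(1, "scene_id", spec.scene_id)
                pf["rel_fix_density"] = patch_response(dens)
                patch_frames.append(pf)

    valid = {(r.participant_id, r.scene_id): True for r in metric_results}
    return analyze_trials(
        metric_results,
        valid,
        categories,
        pd.DataFrame(roi_sal_rows),
        pd.DataFrame(roi_density_rows),
        pd.DataFrame(sal_rank_rows),
        pd.DataFrame(roi_hit_rows),
        area_fractions,
        pd.concat(patch_frames, ignore_index=True),
        pd.DataFrame(fix_count_rows),
        models=models,
        keep_patch_table=keep_patch_table,
    )


def analyze_trials(
    metric_results,
    valid,
    categories,
    roi_scene_saliency: pd.DataFrame,
    roi_density_rows: pd.DataFrame,
    sal_rank_rows: pd.DataFrame,
    roi_hit_rows: pd.DataFrame,
    area_fractions,
    patch_table: pd.DataFrame,
    fixation_stats: pd.DataFrame,
    *,
    models=("0", "1a", "2", "3a", "4", "5a", "6"),
    keep_patch_table: bool = False,
) -> CohortResults:
    """Aggregate per-trial results into the inferential tables."""
    # --- saliency-prediction metrics and paired tests -------------------
    trial_metrics = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in metric_results],
            "scene_id": [r.scene_id for r in metric_results],
            "category": [categories[r.scene_id] for r in metric_results],
            "d_kl": [r.d_kl for r in metric_results],
            "auc": [r.auc for r in metric_results],
            "r": [r.r for r in metric_results],
        }
    )
    by_participant = aggregate_by_category(metric_results, valid, categories)
    paired_rows = []
    wide = by_participant.pivot(index="participant_id", columns="category")
    for metric in ("d_kl", "auc", "r"):
        a = wide[(metric, "social")].to_numpy()
        b = wide[(metric, "non-social")].to_numpy()
        if len(a) >= 3:
            t, df, p, d = stats_rm.paired_t(a, b)
        else:  # too few participants for inference; report means only
            t = p = d = np.nan
            df = len(a) - 1
        paired_rows.append(
            {
                "metric": metric,
                "mean_social": a.mean(),
                "mean_nonsocial": b.mean(),
                "t": t,
                "df": df,
                "p": p,
                "d_paired": d,
            }
        )
    paired_tests = pd.DataFrame(paired_rows)

    # --- ROI analyses ---------------------------------------------------
    roi_participant = (
        roi_density_rows.groupby(["participant_id", "roi"], as_index=False)["rel_norm_density"]
        .mean()
    )
    anova_rows = []
    dens_wide = roi_participant.pivot(index="participant_id", columns="roi", values="rel_norm_density")[
        list(ROI_NAMES)
    ]
    for res in stats_rm.rm_anova_oneway(dens_wide.to_numpy(), factor="roi"):
        anova_rows.append({"analysis": "roi_norm_density", **res.__dict__})
    sal_wide = roi_scene_saliency.pivot(index="scene_id", columns="roi", values="rel_saliency")[
        list(ROI_NAMES)
    ]
    for res in stats_rm.rm_anova_oneway(sal_wide.to_numpy(), factor="roi"):
        anova_rows.append({"analysis": "roi_rel_saliency", **res.__dict__})
    roi_anovas = pd.DataFrame(anova_rows)

    # --- time course ----------------------------------------------------
    tc_sal = summarize_ranked_saliency(sal_rank_rows)
    tc_roi = summarize_roi_frequencies(roi_hit_rows, area_fractions)
    tc_rows = []
    ranks5 = ["1", "2", "3", "4", "5"]
    cube = (
        tc_sal[tc_sal["rank"].isin(ranks5)]
        .pivot_table(index="participant_id", columns=["rank", "category"], values="rel_window_saliency")
    )
    arr = np.stack(
        [
            np.column_stack([cube[(rk, cat)].to_numpy() for cat in ("social", "non-social")])
            for rk in ranks5
        ],
        axis=1,
    )  # (n, 5, 2)
    for res in stats_rm.rm_anova_twoway(arr, factors=("fixation_number", "scene_content")):
        tc_rows.append({"analysis": "window_saliency", **res.__dict__})
    cube2 = (
        tc_roi[tc_roi["rank"].isin(ranks5)]
        .pivot_table(index="participant_id", columns=["rank", "roi"], values="norm_freq")
    )
    arr2 = np.stack(
        [np.column_stack([cube2[(rk, roi)].to_numpy() for roi in ROI_NAMES]) for rk in ranks5],
        axis=1,
    )  # (n, 5, 4)
    for res in stats_rm.rm_anova_twoway(arr2, factors=("fixation_number", "roi")):
        tc_rows.append({"analysis": "roi_frequency", **res.__dict__})
    timecourse_anovas = pd.DataFrame(tc_rows)

    # --- patch mixed models ----------------------------------------------
    design, scaling = standardize_predictors(patch_table)
    fits = {mid: fit_mixed_model(design, mid) for mid in models}
    model_rows = []
    for mid, fit in fits.items():
        for term, eff in fit.fixed_effects.items():
            model_rows.append(
                {
                    "model_id": mid,
                    "term": term,
                    "beta": eff["beta"],
                    "se": eff["se"],
                    "p": eff["p"],
                    "aic": fit.aic,
                    "r2_analog": fit.r2_analog,
                    "loglik_ml": fit.loglik_ml,
                }
            )
    model_table = pd.DataFrame(model_rows)
    ladder = [(a, b) for a, b in LRT_LADDER if a in fits and b in fits]
    lrt_table = compare_models([(fits[a], fits[b]) for a, b in ladder])
    deciles = {
        pred: decile_bin_summary(design.assign(**{pred: patch_table[pred]}), pred)
        for pred in ("dist_center", "rel_saliency", "rel_head", "rel_body")
    }

    return CohortResults(
        trial_metrics=trial_metrics,
        metrics_by_participant=by_participant,
        paired_tests=paired_tests,
        roi_scene_saliency=roi_scene_saliency,
        roi_participant_density=roi_participant,
        roi_anovas=roi_anovas,
        timecourse_saliency=tc_sal,
        timecourse_roi=tc_roi,
        timecourse_anovas=timecourse_anovas,
        model_fits=fits,
        model_table=model_table,
        lrt_table=lrt_table,
        decile_summaries=deciles,
        fixation_stats=fixation_stats,
        patch_table=patch_table if keep_patch_table else None,
    )
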