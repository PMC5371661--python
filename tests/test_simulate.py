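import numpy as np
import pytest

import socialgaze as sg
from socialgaze.events import detect_events
from socialgaze.simulate import (
    CohortConfig,
    GazeModelParams,
    SceneSampler,
    SceneSpec,
    generate_patch_data,
    generate_scene,
    scene_specs_for_cohort,
    simulate_fixation_sequence,
    simulate_raw_samples,
)


class TestGenerateScene:
    def test_same_seed_bit_identical(self):
        a = generate_scene(SceneSpec(scene_id="s"), (1, 2))
        b = generate_scene(SceneSpec(scene_id="s"), (1, 2))
        np.testing.assert_array_equal(a.saliency.values, b.saliency.values)
        np.testing.assert_array_equal(a.head_mask, b.head_mask)

    def test_mask_coverage_matches_spec(self):
        spec = SceneSpec(head_frac=0.02, body_frac=0.09, scene_id="s")
        scene = generate_scene(spec, 3)
        assert scene.head_mask.mean() == pytest.approx(0.02, abs=0.002)
        assert scene.body_mask.mean() == pytest.approx(0.09, abs=0.005)
        assert not (scene.head_mask & scene.body_mask).any()

    def test_social_feature_distance_from_center(self, geometry):
        spec = SceneSpec(scene_id="s")
        for seed in range(3):
            scene = generate_scene(spec, (7, seed))
            ys, xs = np.nonzero(scene.head_mask)
            d_px = np.hypot(xs.mean() - 600, ys.mean() - 450)
            d_deg = d_px / geometry.px_per_deg_x
            assert d_deg == pytest.approx(9.6, abs=1.5)

    def test_constructed_roi_saliency_ordering(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 11)
        rs = sg.build_roi_set(scene.head_mask, scene.body_mask, scene.saliency)
        rel = {s.roi: s.rel_saliency for s in sg.roi_relative_saliency(rs, scene.saliency)}
        assert rel["higher"] > rel["head"] > rel["lower"]
        assert rel["head"] == pytest.approx(rel["body"], rel=0.1)

    def test_nonsocial_scene_has_no_masks(self):
        scene = generate_scene(SceneSpec(category="non-social", scene_id="n"), 5)
        assert scene.head_mask is None and scene.body_mask is None

    def test_saliency_in_unit_range(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 13)
        assert scene.saliency.values.min() == 0.0
        assert scene.saliency.values.max() == 1.0


class TestFixationSequence:
    def test_determinism(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 1)
        a = simulate_fixation_sequence(scene, GazeModelParams(), np.random.default_rng(5))
        b = simulate_fixation_sequence(scene, GazeModelParams(), np.random.default_rng(5))
        assert a == b

    def test_pure_head_targeting_without_amplitude_cap(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 2)
        params = GazeModelParams(
            w_head=1.0, w_body=0.0, w_saliency=0.0, w_center=0.0,
            early_social_boost=1.0, head_dwell_damping=1.0,
            saccade_amp_mean_deg=50.0, saccade_amp_sd_deg=1.0,
        )
        fx = simulate_fixation_sequence(scene, params, np.random.default_rng(3))
        hits = [scene.head_mask[int(round(f.y)), int(round(f.x))] for f in fx[1:]]
        assert np.mean(hits) > 0.9  # all but landing noise at head borders

    def test_default_fixation_count_in_calibrated_band(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 4)
        sampler = SceneSampler(scene)
        counts = [
            len(simulate_fixation_sequence(scene, GazeModelParams(), np.random.default_rng(i), sampler=sampler))
            for i in range(15)
        ]
        assert 28 <= np.mean(counts) <= 35

    def test_durations_truncated_at_forty_ms(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 4)
        params = GazeModelParams(fix_duration_mean_ms=60, fix_duration_sd_ms=50)
        fx = simulate_fixation_sequence(scene, params, np.random.default_rng(9))
        assert all(f.duration >= 40 for f in fx)

    def test_zero_weights_error(self):
        scene = generate_scene(SceneSpec(scene_id="s"), 4)
        with pytest.raises(ValueError):
            GazeModelParams(w_head=0, w_body=0, w_saliency=0, w_center=0)

    def test_saccade_amplitudes_near_calibrated_mean(self, geometry):
        scene = generate_scene(SceneSpec(category="non-social", scene_id="n"), 6)
        sampler = SceneSampler(scene)
        amps = []
        for i in range(10):
            fx = simulate_fixation_sequence(scene, GazeModelParams(), np.random.default_rng(i), sampler=sampler)
            for a, b in zip(fx, fx[1:]):
                amps.append(np.hypot(b.x - a.x, b.y - a.y) / geometry.px_per_deg_x)
        assert np.mean(amps) == pytest.approx(4.7, abs=1.0)


class TestRawSamples:
    def test_blink_insertion_flags_invalid_trial(self, geometry, rng):
        scene = generate_scene(SceneSpec(scene_id="s"), 8)
        fx = simulate_fixation_sequence(scene, GazeModelParams(), np.random.default_rng(1))
        params = GazeModelParams(jitter_sd_deg=0.0, drift_sd_px=0.0)
        samples = simulate_raw_samples(
            fx, params, rng, geometry=geometry, drift=(0, 0),
            blink_windows=[(3000, 5200)],  # 2.2 s
        )
        ev = detect_events(samples, geometry, offset_ms=10_000)
        assert not ev.valid

    def test_thousand_hz_grid(self, geometry, rng):
        fx = [sg.Fixation(300, 800, 400.0, 300.0)]
        samples = simulate_raw_samples(
            fx, GazeModelParams(), rng, geometry=geometry, trial_duration_ms=1000, baseline_ms=200
        )
        ts = np.array([s.t for s in samples])
        assert ts[0] == -200 and ts[-1] == 999
        assert (np.diff(ts) == 1).all()


class TestGeneratePatchData:
    def test_noiseless_limit_exact(self):
        truth = {"intercept": 1.0, "dist_center": -0.3, "rel_saliency": 0.15,
                 "rel_head": 0.5, "rel_body": 0.2}
        design, meta = generate_patch_data(3, 4, truth, 0.0, 0.0, 0.0, seed=1)
        X = np.column_stack(
            [np.ones(len(design))]
            + [design[t].to_numpy() for t in ("dist_center", "rel_saliency", "rel_head", "rel_body")]
        )
        y = design["rel_fix_density"].to_numpy()
        resid = y - X @ np.array([1.0, -0.3, 0.15, 0.5, 0.2])
        assert np.abs(resid).max() < 1e-10
        assert meta["betas"] == truth

    def test_null_betas_rarely_significant(self):
        import warnings

        from socialgaze.patches import fit_mixed_model

        flags = []
        for rep in range(10):
            design, _ = generate_patch_data(4, 5, {"intercept": 0.0}, 0.0, 0.0, 0.3, seed=(50, rep))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_mixed_model(design, "4")
            for term in ("dist_center", "rel_saliency", "rel_head", "rel_body"):
                eff = fit.fixed_effects[term]
                flags.append(abs(eff["beta"]) < 2 * eff["se"])
        assert np.mean(flags) >= 0.85

    def test_predictor_structure(self):
        design, _ = generate_patch_data(2, 3, {"intercept": 1.0}, 0.0, 0.0, 0.1, seed=4)
        assert len(design) == 2 * 3 * 108
        # scene-level predictors are identical across participants
        a = design[design.participant_id == "p000"]["rel_head"].to_numpy()
        b = design[design.participant_id == "p001"]["rel_head"].to_numpy()
        np.testing.assert_array_equal(a, b)


def test_scene_specs_layout():
    specs = scene_specs_for_cohort(CohortConfig(n_social=3, n_nonsocial=2))
    assert [s.category for s in specs] == ["social"] * 3 + ["non-social"] * 2
    assert len({s.scene_id for s in specs}) == 5
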