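import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialgaze.events import (
    GazeSample,
    detect_events,
    drift_correct,
    recursive_outlier_filter,
)
from socialgaze.geometry import PixelPoint
from socialgaze.simulate import GazeModelParams, simulate_raw_samples
from socialgaze.events import Fixation, TrialEvents


def _stationary(t0, t1, x, y, valid=True):
    return [GazeSample(t, x, y, valid) for t in range(t0, t1)]


class TestDetectEvents:
    def test_single_stationary_fixation(self, geometry):
        samples = _stationary(0, 1000, 600.0, 450.0)
        ev = detect_events(samples, geometry, offset_ms=1000)
        assert len(ev.fixations) == 1
        assert not ev.saccades and not ev.blinks
        f = ev.fixations[0]
        assert (f.x, f.y) == (600.0, 450.0)
        assert f.duration == 1000

    def test_two_fixations_one_saccade(self, geometry):
        # 400 ms at A, 40 ms linear traverse of 5 degrees (~125 deg/s), 400 ms at B
        dx = geometry.deg_to_px(5.0, "x")
        samples = _stationary(0, 400, 300.0, 450.0)
        for i, t in enumerate(range(400, 440)):
            samples.append(GazeSample(t, 300.0 + dx * (i + 1) / 40.0, 450.0))
        samples += _stationary(440, 840, 300.0 + dx, 450.0)
        ev = detect_events(samples, geometry, offset_ms=840)
        assert len(ev.fixations) == 2
        assert len(ev.saccades) == 1
        assert ev.saccades[0].amplitude_deg == pytest.approx(5.0, abs=0.5)
        assert ev.fixations[0].x == pytest.approx(300.0, abs=1.0)
        assert ev.fixations[1].x == pytest.approx(300.0 + dx, abs=1.0)

    def test_blink_rule_flags_invalid_trial(self, geometry):
        samples = _stationary(0, 3000, 600.0, 450.0)
        samples += _stationary(3000, 5500, 600.0, 450.0, valid=False)  # 2.5 s blink
        samples += _stationary(5500, 8000, 600.0, 450.0)
        ev = detect_events(samples, geometry, offset_ms=8000)
        assert not ev.valid
        assert ev.blinks == [(3000, 5500)]

    def test_short_blink_keeps_trial_valid(self, geometry):
        samples = _stationary(0, 3000, 600.0, 450.0)
        samples += _stationary(3000, 4500, 600.0, 450.0, valid=False)  # 1.5 s
        samples += _stationary(4500, 8000, 600.0, 450.0)
        ev = detect_events(samples, geometry, offset_ms=8000)
        assert ev.valid

    def test_event_partition_covers_scene_time(self, geometry):
        """Every in-scene sample is fixation, saccade, blink, or a short run."""
        dx = geometry.deg_to_px(6.0, "x")
        samples = _stationary(0, 300, 400.0, 400.0)
        for i, t in enumerate(range(300, 330)):
            samples.append(GazeSample(t, 400.0 + dx * (i + 1) / 30.0, 400.0))
        samples += _stationary(330, 600, 400.0 + dx, 400.0, valid=True)
        samples += _stationary(600, 700, 400.0 + dx, 400.0, valid=False)
        samples += _stationary(700, 1000, 400.0 + dx, 400.0)
        ev = detect_events(samples, geometry, offset_ms=1000)
        covered = np.zeros(1000, dtype=int)
        for f in ev.fixations:
            covered[f.t_start : f.t_end] += 1
        for s in ev.saccades:
            covered[s.t_start : s.t_end] += 1
        for a, b in ev.blinks:
            covered[a:b] += 1
        assert covered.max() <= 1  # non-overlapping events

    def test_rejects_empty_and_tiny_input(self, geometry):
        with pytest.raises(ValueError):
            detect_events([], geometry)
        with pytest.raises(ValueError):
            detect_events(_stationary(0, 10, 0, 0), geometry)

    def test_all_missing_trial_invalid(self, geometry):
        ev = detect_events(_stationary(0, 3000, 0.0, 0.0, valid=False), geometry, offset_ms=3000)
        assert not ev.valid
        assert not ev.fixations


class TestRecursiveOutlierFilter:
    @pytest.mark.parametrize(
        "values,expected_removed",
        [
            ([1, 2, 3, 4, 50], [50.0]),
            ([5, 5, 5, 5, 5], []),
            ([-100, 0, 0, 0, 0, 100], [100.0, -100.0]),
        ],
    )
    def test_hand_traced_fixtures(self, values, expected_removed):
        kept, removed = recursive_outlier_filter(values)
        assert sorted(removed) == sorted(expected_removed)
        assert sorted(kept + removed) == sorted(float(v) for v in values)

    def test_short_input_unchanged(self):
        with pytest.warns(UserWarning):
            kept, removed = recursive_outlier_filter([1.0, 2.0])
        assert kept == [1.0, 2.0] and removed == []

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=3, max_size=40))
    def test_idempotent_and_partition(self, values):
        kept, removed = recursive_outlier_filter(values)
        assert sorted(kept + removed) == sorted(float(v) for v in values)
        kept2, removed2 = recursive_outlier_filter(kept)
        assert removed2 == []
        assert sorted(kept2) == sorted(kept)


def _trial_with_baseline(bx, by, fixations):
    return TrialEvents(
        "p0", f"s{bx}_{by}", fixations=list(fixations), baseline_mean=PixelPoint(bx, by)
    )


class TestDriftCorrect:
    def test_zero_offset_leaves_fixations(self):
        cross = PixelPoint(600.0, 450.0)
        trials = [
            _trial_with_baseline(600.0, 450.0, [Fixation(0, 100, 100.0, 200.0)])
            for _ in range(5)
        ]
        out = drift_correct(trials, cross)
        assert out[0].fixations[0].x == 100.0
        assert out[0].fixations[0].y == 200.0
        assert not out[0].baseline_replaced

    def test_constant_offset_shifts_fixations(self):
        cross = PixelPoint(600.0, 450.0)
        trials = [
            _trial_with_baseline(610.0, 445.0, [Fixation(0, 100, 100.0, 200.0)])
            for _ in range(5)
        ]
        out = drift_correct(trials, cross)
        assert out[0].fixations[0].x == pytest.approx(90.0)
        assert out[0].fixations[0].y == pytest.approx(205.0)

    def test_outlier_baseline_replaced_by_mean_of_others(self):
        cross = PixelPoint(600.0, 450.0)
        trials = [_trial_with_baseline(600.0 + d, 450.0, [Fixation(0, 100, 0.0, 0.0)])
                  for d in (0.0, 1.0, -1.0, 0.5, -0.5)]
        trials.append(_trial_with_baseline(900.0, 450.0, [Fixation(0, 100, 0.0, 0.0)]))
        out = drift_correct(trials, cross)
        assert out[-1].baseline_replaced
        assert not any(tr.baseline_replaced for tr in out[:-1])
        # replacement baseline = mean of the five kept baselines (x = 600.0)
        assert out[-1].baseline_mean.x == pytest.approx(600.0)
        assert out[-1].fixations[0].x == pytest.approx(0.0)

    def test_missing_baseline_replaced(self):
        cross = PixelPoint(600.0, 450.0)
        trials = [_trial_with_baseline(600.0, 450.0, []) for _ in range(4)]
        trials.append(
            TrialEvents("p0", "sx", fixations=[Fixation(0, 50, 5.0, 5.0)], baseline_mean=None)
        )
        out = drift_correct(trials, cross)
        assert out[-1].baseline_replaced

    def test_no_baselines_is_error(self):
        trials = [TrialEvents("p0", "s0", fixations=[], baseline_mean=None)]
        with pytest.raises(ValueError):
            drift_correct(trials, PixelPoint(600, 450))


class TestSampleLevelRoundTrip:
    def test_noiseless_trace_recovers_fixations_exactly(self, geometry, rng):
        params = GazeModelParams(jitter_sd_deg=0.0, drift_sd_px=0.0, blink_rate_per_trial=0.0)
        truth = [
            Fixation(250, 600, 300.0, 300.0),
            Fixation(630, 950, 500.0, 420.0),
            Fixation(990, 1400, 700.0, 600.0),
        ]
        samples = simulate_raw_samples(
            truth, params, rng, geometry=geometry, trial_duration_ms=1500,
            drift=(0, 0), blink_windows=[],
        )
        ev = detect_events(samples, geometry, offset_ms=1500)
        assert len(ev.fixations) == len(truth)
        for f, g in zip(truth, ev.fixations):
            assert g.x == pytest.approx(f.x, abs=0.5)
            assert g.y == pytest.approx(f.y, abs=0.5)

    def test_drift_offset_recovered_within_tenth_degree(self, geometry, rng):
        params = GazeModelParams(jitter_sd_deg=0.0, blink_rate_per_trial=0.0)
        truth = [Fixation(300, 700, 400.0, 350.0), Fixation(760, 1200, 800.0, 500.0)]
        samples = simulate_raw_samples(
            truth, params, rng, geometry=geometry, trial_duration_ms=1500,
            drift=(12.0, -8.0), blink_windows=[],
        )
        ev = detect_events(samples, geometry, offset_ms=1500, participant_id="p0", scene_id="s0")
        assert ev.baseline_mean is not None
        out = drift_correct([ev], geometry.center)[0]
        tol = geometry.deg_to_px(0.1, "x")
        for f, g in zip(truth, out.fixations):
            assert abs(g.x - f.x) < tol
            assert abs(g.y - f.y) < tol
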