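"""Event detection and drift correction for 1000-Hz gaze samples.

Samples are parsed into blinks (missing pupil), saccades (velocity or
acceleration above threshold) and fixations (the stationary periods in
between). Trials accumulate a validity flag from total blink time, and
fixation coordinates are drift-corrected per participant against the mean
gaze position during a pre-stimulus central-cross baseline, with a recursive
outlier filter protecting the baseline distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import PixelPoint, ViewingGeometry

__all__ = [
    "GazeSample",
    "Fixation",
    "Saccade",
    "TrialEvents",
    "detect_events",
    "recursive_outlier_filter",
    "drift_correct",
]

#: trials with >= this much blink time during scene presentation are invalid
MAX_BLINK_MS = 2000
#: runs of non-saccade, non-blink samples shorter than this are not fixations
MIN_FIXATION_MS = 40


@dataclass(frozen=True)
class GazeSample:
    t: int  # ms
    x: float  # px
    y: float  # px
    pupil_valid: bool = True


@dataclass(frozen=True)
class Fixation:
    t_start: int
    t_end: int
    x: float
    y: float

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class Saccade:
    t_start: int
    t_end: int
    amplitude_deg: float


@dataclass
class TrialEvents:
    """Parsed events for one participant x scene viewing."""

    participant_id: str
    scene_id: str
    fixations: list[Fixation]
    saccades: list[Saccade] = field(default_factory=list)
    blinks: list[tuple[int, int]] = field(default_factory=list)
    valid: bool = True
    baseline_mean: PixelPoint | None = None
    baseline_replaced: bool = False


def _samples_to_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t = np.asarray([s.t for s in samples], dtype=np.int64)
    x = np.asarray([s.x for s in samples], dtype=float)
    y = np.asarray([s.y for s in samples], dtype=float)
    ok = np.asarray([s.pupil_valid for s in samples], dtype=bool)
    if len(t) and np.any(np.diff(t) <= 0):
        raise ValueError("sample timestamps must be strictly increasing")
    return t, x, y, ok


def _runs(mask: np.ndarray):
    """Yield (start_idx, end_idx_exclusive) for maximal True runs."""
    if mask.size == 0:
        return
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for a, b in zip(edges[::2], edges[1::2]):
        yield int(a), int(b)


def detect_events(
    samples,
    geometry: ViewingGeometry,
    *,
    onset_ms: int = 0,
    offset_ms: int | None = None,
    v_thresh: float = 30.0,
    a_thresh: float = 8000.0,
    min_fixation_ms: int = MIN_FIXATION_MS,
    blink_pad_ms: int = 0,
    participant_id: str = "",
    scene_id: str = "",
) -> TrialEvents:
    """Classify raw samples into fixations, saccades and blinks.

    Velocity and acceleration are estimated by central differences over a
    5-sample window (the two-sided difference spans 4 ms at 1000 Hz), in
    degrees via the viewing geometry. A sample is a saccade sample if its
    speed exceeds ``v_thresh`` (deg/s) OR its acceleration magnitude exceeds
    ``a_thresh`` (deg/s^2). Blinks are maximal runs of missing-pupil samples,
    optionally padded by ``blink_pad_ms`` on each side. Remaining runs of at
    least ``min_fixation_ms`` become fixations positioned at the mean of
    their member samples.

    Only fixations that start at or after ``onset_ms`` are kept; fixations
    straddling ``offset_ms`` are truncated there. The trial is valid when
    total blink time inside [onset, offset) is below 2 s.
    """
    if len(samples) == 0:
        raise ValueError("empty sample list")
    t, x, y, ok = _samples_to_arrays(samples)
    n = len(t)
    if offset_ms is None:
        offset_ms = int(t[-1]) + 1
    if n < 20:
        raise ValueError(f"need >= 20 samples, got {n}")

    blink = ~ok
    if blink_pad_ms > 0:
        pad = int(blink_pad_ms)
        padded = blink.copy()
        for a, b in _runs(blink):
            padded[max(0, a - pad) : min(n, b + pad)] = True
        blink = padded

    events = TrialEvents(participant_id, scene_id, fixations=[])
    in_scene = (t >= onset_ms) & (t < offset_ms)
    blink_ms = int(np.count_nonzero(blink & in_scene))
    events.blinks = [(int(t[a]), int(t[b - 1]) + 1) for a, b in _runs(blink)]
    events.valid = blink_ms < MAX_BLINK_MS

    if np.all(blink):
        events.valid = False
        return events

    # degrees relative to an arbitrary origin; scale is all that matters
    xd = x / geometry.px_per_deg_x
    yd = y / geometry.px_per_deg_y
    dt = np.gradient(t.astype(float))  # ms
    # 5-sample central window: average the 2-step two-sided difference
    vx = _central_diff(xd, t) * 1000.0  # deg/s
    vy = _central_diff(yd, t) * 1000.0
    speed = np.hypot(vx, vy)
    acc = _central_diff(speed, t) * 1000.0  # deg/s^2
    del dt

    sacc = (speed > v_thresh) | (np.abs(acc) > a_thresh)
    sacc &= ~blink  # blink wins

    for a, b in _runs(sacc):
        amp = float(np.hypot(xd[b - 1] - xd[a], yd[b - 1] - yd[a]))
        events.saccades.append(Saccade(int(t[a]), int(t[b - 1]) + 1, amp))

    fixlike = ~sacc & ~blink
    all_fix: list[Fixation] = []
    fix_sample_mask = np.zeros(n, dtype=bool)
    for a, b in _runs(fixlike):
        if t[b - 1] + 1 - t[a] < min_fixation_ms:
            continue
        all_fix.append(
            Fixation(int(t[a]), int(t[b - 1]) + 1, float(np.mean(x[a:b])), float(np.mean(y[a:b])))
        )
        fix_sample_mask[a:b] = True

    # scene-window fixations: started after onset, truncated at offset
    for f in all_fix:
        if f.t_start < onset_ms or f.t_start >= offset_ms:
            continue
        events.fixations.append(replace(f, t_end=min(f.t_end, offset_ms)))

    # baseline: mean position of fixation-classified samples in the 300 ms
    # before scene onset (used later by drift_correct)
    base = fix_sample_mask & (t >= onset_ms - 300) & (t < onset_ms)
    if np.any(base):
        events.baseline_mean = PixelPoint(float(np.mean(x[base])), float(np.mean(y[base])))
    return events


def _central_diff(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Two-step central difference (5-sample window), per-ms units."""
    n = len(v)
    out = np.zeros(n)
    if n < 5:
        return out
    out[2:-2] = (v[4:] - v[:-4]) / (t[4:] - t[:-4])
    out[:2] = out[2]
    out[-2:] = out[-3]
    return out


def recursive_outlier_filter(values) -> tuple[list[float], list[float]]:
    """Recursively discard extremes lying beyond mean +/- 3 SD of the rest.

    At each step the current minimum and maximum are removed from the pool
    and each is tested against the mean +/- 3 standard deviations (n-1
    denominator) of the remaining values; an extreme strictly beyond the
    bound is discarded permanently, a conforming extreme rejoins the pool.
    Iteration stops when neither extreme is removed. Inputs with fewer than
    3 values are returned unchanged.

    Returns
    -------
    (kept, removed) : tuple of lists
        Partition of the input as a multiset.
    """
    pool = [float(v) for v in values]
    removed: list[float] = []
    if len(pool) < 3:
        warnings.warn("recursive_outlier_filter: fewer than 3 values, returned unchanged")
        return pool, removed
    while len(pool) >= 3:
        pool.sort()
        lo, hi = pool[0], pool[-1]
        rest = pool[1:-1]
        m = float(np.mean(rest))
        sd = float(np.std(rest, ddof=1)) if len(rest) > 1 else 0.0
        out_lo = lo < m - 3 * sd
        out_hi = hi > m + 3 * sd
        if out_hi:
            pool.pop()
            removed.append(hi)
        if out_lo:
            pool.pop(0)
            removed.append(lo)
        if not (out_lo or out_hi):
            break
    return pool, removed


def drift_correct(
    trials: list[TrialEvents],
    cross_position: PixelPoint,
    *,
    baseline_window_ms: int = 300,
) -> list[TrialEvents]:
    """Drift-correct one participant's trials against the central cross.

    Per trial the baseline is the mean fixation-sample position during the
    ``baseline_window_ms`` before scene onset (recorded by
    :func:`detect_events`). The recursive outlier filter runs over this
    participant's baseline x and y distributions; trials whose baseline was
    flagged on either axis, or is missing, have it replaced by the mean of
    the valid baselines and are marked ``baseline_replaced``. Every fixation
    is then shifted by ``cross_position - baseline_mean``.
    """
    del baseline_window_ms  # window applied at detection time; kept for API clarity
    xs = [t.baseline_mean.x for t in trials if t.baseline_mean is not None]
    ys = [t.baseline_mean.y for t in trials if t.baseline_mean is not None]
    if not xs:
        raise ValueError("no trial has valid baseline position data")
    _, removed_x = recursive_outlier_filter(xs)
    _, removed_y = recursive_outlier_filter(ys)
    bad_x = _multiset(removed_x)
    bad_y = _multiset(removed_y)

    flagged: list[bool] = []
    for tr in trials:
        if tr.baseline_mean is None:
            flagged.append(True)
            continue
        fx = _take(bad_x, tr.baseline_mean.x) or _take(bad_y, tr.baseline_mean.y)
        flagged.append(fx)

    good = [tr.baseline_mean for tr, f in zip(trials, flagged) if not f]
    if not good:
        raise ValueError("all baselines flagged as outliers")
    mean_good = PixelPoint(
        float(np.mean([p.x for p in good])), float(np.mean([p.y for p in good]))
    )

    out: list[TrialEvents] = []
    for tr, f in zip(trials, flagged):
        base = mean_good if f else tr.baseline_mean
        dx = cross_position.x - base.x
        dy = cross_position.y - base.y
        fixes = [replace(fx, x=fx.x + dx, y=fx.y + dy) for fx in tr.fixations]
        new = replace(tr, fixations=fixes, baseline_mean=base, baseline_replaced=f)
        out.append(new)
    return out


def _multiset(values: list[float]) -> dict[float, int]:
    d: dict[float, int] = {}
    for v in values:
        d[v] = d.get(v, 0) + 1
    return d


def _take(ms: dict[float, int], v: float) -> bool:
    if ms.get(v, 0) > 0:
        ms[v] -= 1
        return True
    return False
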