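"""File formats: gaze TSV, EyeLink-ASC-style samples, ROI mask PNGs, config.

Gaze samples travel as a plain TSV with header
``participant_id  scene_id  t_ms  x_px  y_px  pupil_valid``; ROI masks are
8-bit indexed PNGs with label codes 0 = background, 1 = head, 2 = body.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .events import GazeSample

__all__ = [
    "write_gaze_tsv",
    "read_gaze_tsv",
    "read_asc_samples",
    "write_roi_masks",
    "read_roi_masks",
    "load_config",
    "dump_config",
]

GAZE_COLUMNS = ["participant_id", "scene_id", "t_ms", "x_px", "y_px", "pupil_valid"]


def write_gaze_tsv(path, trials: dict[tuple[str, str], list[GazeSample]]) -> None:
    """Write {(participant_id, scene_id): samples} as one TSV."""
    frames = []
    for (pid, sid), samples in trials.items():
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "scene_id": sid,
                    "t_ms": [s.t for s in samples],
                    "x_px": [s.x for s in samples],
                    "y_px": [s.y for s in samples],
                    "pupil_valid": [int(s.pupil_valid) for s in samples],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gaze_tsv(path) -> dict[tuple[str, str], list[GazeSample]]:
    df = pd.read_csv(path, sep="\t")
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gaze TSV {path} lacks columns {sorted(missing)}")
    out: dict[tuple[str, str], list[GazeSample]] = {}
    for (pid, sid), grp in df.groupby(["participant_id", "scene_id"], sort=False):
        out[(str(pid), str(sid))] = [
            GazeSample(int(t), float(x), float(y), bool(v))
            for t, x, y, v in zip(grp["t_ms"], grp["x_px"], grp["y_px"], grp["pupil_valid"])
        ]
    return out


def read_asc_samples(path) -> list[GazeSample]:
    """Parse monocular sample lines of an EyeLink ASC export.

    Sample lines start with an integer timestamp followed by x, y and pupil
    size; missing data is marked by dots. Event/message lines are skipped.
    """
    samples = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue
            t = int(parts[0])
            if len(parts) < 4 or parts[1].startswith("."):
                samples.append(GazeSample(t, np.nan, np.nan, False))
                continue
            try:
                x, y, pupil = float(parts[1]), float(parts[2]), float(parts[3])
            except ValueError:
                samples.append(GazeSample(t, np.nan, np.nan, False))
                continue
            samples.append(GazeSample(t, x, y, pupil > 0))
    return samples


def write_roi_masks(path, head_mask: np.ndarray, body_mask: np.ndarray) -> None:
    """8-bit indexed PNG: 0 background, 1 head, 2 body (head wins overlaps)."""
    label = np.zeros(head_mask.shape, dtype=np.uint8)
    label[np.asarray(body_mask, bool)] = 2
    label[np.asarray(head_mask, bool)] = 1
    img = Image.fromarray(label, mode="P")
    img.putpalette([0, 0, 0, 255, 64, 64, 64, 64, 255] + [0] * (256 * 3 - 9))
    img.save(path)


def read_roi_masks(path) -> tuple[np.ndarray, np.ndarray]:
    label = np.array(Image.open(path))
    return label == 1, label == 2


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
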