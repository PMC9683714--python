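"""Behavioral and assay statistics.

Social score for chamber-based social-preference tests: the mean per-frame
position along the chamber axis, affinely mapped so the wall adjoining the
social-stimulus compartment is +1 and the opposite (empty) wall is −1.
Open-field metrics (percent time in the center zone, mean velocity),
ChIP-qPCR adjusted fold change, and the hole-board coefficient of
exploratory variation (SD/mean of per-hole head pokes, a perseveration
index) round out the assay toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Trajectory",
    "ArenaGeometry",
    "PokeCounts",
    "social_score",
    "open_field_metrics",
    "adjusted_fold_change",
    "exploratory_variation",
]

#: video frame rate of the chamber imaging rig (frames/second)
DEFAULT_FRAME_RATE = 7.5


@dataclass
class Trajectory:
    """Per-frame (x, y) positions at a fixed frame rate."""

    frames: np.ndarray  # shape (n, 2)
    frame_rate: float = DEFAULT_FRAME_RATE

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[1] != 2:
            raise ValueError("frames must be an (n, 2) array of x, y positions")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.frames[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.frames[:, 1]

    @classmethod
    def from_csv(
        cls, path: str | Path, frame_rate: float = DEFAULT_FRAME_RATE
    ) -> "Trajectory":
        """Read a tracking CSV with header ``frame,x,y`` (one row per frame)."""
        df = pd.read_csv(path)
        missing = {"x", "y"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        if "frame" in df.columns:
            df = df.sort_values("frame")
        return cls(frames=df[["x", "y"]].to_numpy(), frame_rate=frame_rate)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"frame": np.arange(len(self)), "x": self.x, "y": self.y}
        )
        df.to_csv(path, index=False)


@dataclass
class ArenaGeometry:
    """Test-arena geometry.

    ``y_social`` and ``y_empty`` are the y coordinates of the wall adjoining
    the social-stimulus compartment and of the opposite wall.  For the open
    field, ``center_zone`` is an axis-aligned rectangle
    (x_min, x_max, y_min, y_max); its boundary counts as inside.
    """

    y_social: float
    y_empty: float
    center_zone: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.y_social == self.y_empty:
            raise ValueError("y_social and y_empty must differ")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ArenaGeometry":
        cfg = yaml.safe_load(Path(path).read_text())
        zone = cfg.get("center_zone")
        return cls(
            y_social=float(cfg["y_social"]),
            y_empty=float(cfg["y_empty"]),
            center_zone=tuple(float(v) for v in zone) if zone else None,
        )


def social_score(
    traj: Trajectory, arena: ArenaGeometry, clamp_tol: float = 0.01
) -> float:
    """Mean per-frame chamber position mapped to [−1, +1].

    The wall next to the social stimulus maps to +1, the empty-compartment
    wall to −1, and the chamber middle to 0; the score is the mean of the
    mapped y positions over all frames, so higher scores mean the subject
    stayed closer to the social stimulus.  Tracker jitter up to
    ``clamp_tol`` × chamber length beyond either wall is clamped; larger
    excursions are an error.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    lo = min(arena.y_social, arena.y_empty)
    hi = max(arena.y_social, arena.y_empty)
    tol = clamp_tol * (hi - lo)
    y = traj.y
    if np.any(y < lo - tol) or np.any(y > hi + tol):
        worst = y[np.argmax(np.maximum(lo - y, y - hi))]
        raise ValueError(
            f"y positions outside the arena by more than {tol:g}: e.g. {worst:g}"
        )
    y = np.clip(y, lo, hi)
    # affine map: y_empty -> -1, y_social -> +1 (orientation-agnostic)
    scaled = 2.0 * (y - arena.y_empty) / (arena.y_social - arena.y_empty) - 1.0
    return float(np.mean(scaled))


def open_field_metrics(
    traj: Trajectory, arena: ArenaGeometry
) -> tuple[float, float]:
    """(percent time in center zone, mean velocity).

    Center-zone membership is boundary-inclusive.  Mean velocity is total
    path length (sum of frame-to-frame Euclidean displacements) divided by
    the recording duration (n−1 inter-frame intervals); needs >=2 frames.
    """
    if arena.center_zone is None:
        raise ValueError("arena has no center_zone defined")
    if len(traj) < 2:
        raise ValueError("velocity needs at least two frames")
    x0, x1, y0, y1 = arena.center_zone
    inside = (
        (traj.x >= min(x0, x1)) & (traj.x <= max(x0, x1))
        & (traj.y >= min(y0, y1)) & (traj.y <= max(y0, y1))
    )
    pct_center = 100.0 * float(np.mean(inside))
    steps = np.linalg.norm(np.diff(traj.frames, axis=0), axis=1)
    duration = (len(traj) - 1) / traj.frame_rate
    return pct_center, float(steps.sum() / duration)


def adjusted_fold_change(
    fc_target_treat: float,
    fc_ref_treat: float,
    fc_target_ctrl: float,
    fc_ref_ctrl: float,
) -> float:
    """Reference-gene-adjusted fold change for ChIP-qPCR.

    (target FC / reference FC) in the treatment sample divided by the same
    ratio in the vehicle-control sample; all inputs must be positive.
    """
    vals = (fc_target_treat, fc_ref_treat, fc_target_ctrl, fc_ref_ctrl)
    if any(v <= 0 for v in vals):
        raise ValueError(f"fold changes must be positive, got {vals}")
    return (fc_target_treat / fc_ref_treat) / (fc_target_ctrl / fc_ref_ctrl)


@dataclass
class PokeCounts:
    """Per-hole head-poke counts from a hole-board session (default 16 holes)."""

    counts: Sequence[int]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("need counts for at least two holes")
        if np.any(arr < 0):
            raise ValueError("poke counts must be nonnegative")
        self.counts = arr.astype(float)


def exploratory_variation(pokes: PokeCounts) -> float:
    """Coefficient of exploratory variation: sample SD / mean of per-hole pokes.

    Uses the n−1 (sample) standard deviation.  Scale-invariant: multiplying
    every count by a positive constant leaves the coefficient unchanged.
    All-zero counts (mean 0) are undefined and raise.
    """
    arr = np.asarray(pokes.counts, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("mean poke count is zero; coefficient undefined")
    return float(arr.std(ddof=1) / mean)
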