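"""Freezing, open-field and object-recognition behavior scoring.

Freezing is scored from a per-frame motion index the way automated
fear-conditioning software does it: a frame is immobile when its motion
index is strictly below a threshold (default 18 arbitrary units), and a
maximal immobile run counts as freezing only when it lasts at least a
minimum number of frames (default 30 frames at 30 fps, i.e. immobility
lasting at least 1 s).  Runs are evaluated on the uncut trace, so a
freezing bout that spans a tone onset is not erased; its frames are then
attributed to their containing intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataQualityError, ValidationError
from .session import EventSchedule


@dataclass(frozen=True)
class MotionTrace:
    """Per-frame motion index (arbitrary units >= 0) at a fixed frame rate."""

    motion_index: np.ndarray
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        mi = np.asarray(self.motion_index, dtype=np.float64)
        object.__setattr__(self, "motion_index", mi)
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")
        if not np.all(np.isfinite(mi)):
            raise DataQualityError("motion index contains non-finite values")
        if np.any(mi < 0):
            raise ValidationError("motion index must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.motion_index.shape[0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"frame": np.arange(self.n_frames), "motion_index": self.motion_index}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 30.0) -> "MotionTrace":
        df = pd.read_csv(path)
        return cls(df["motion_index"].to_numpy(), frame_rate)


@dataclass(frozen=True)
class FreezingParams:
    threshold: float = 18.0
    min_freeze_frames: int = 30

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.min_freeze_frames < 1:
            raise ValidationError("min_freeze_frames must be >= 1")


def immobile_runs(immobile: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    immobile = np.asarray(immobile, dtype=bool)
    if immobile.size == 0:
        return []
    edges = np.flatnonzero(np.diff(immobile.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    lengths = np.diff(np.concatenate((starts, [immobile.size])))
    return [
        (int(s), int(n)) for s, n in zip(starts, lengths) if immobile[s]
    ]


def freezing_mask(motion: MotionTrace, params: FreezingParams) -> np.ndarray:
    """Boolean per-frame mask of frames belonging to qualifying freezing bouts.

    A frame is immobile iff ``motion_index < threshold`` (the boundary value
    counts as motion); only maximal immobile runs of at least
    ``min_freeze_frames`` frames qualify as freezing.
    """
    immobile = motion.motion_index < params.threshold
    mask = np.zeros(motion.n_frames, dtype=bool)
    for start, length in immobile_runs(immobile):
        if length >= params.min_freeze_frames:
            mask[start : start + length] = True
    return mask


def score_freezing(
    motion: MotionTrace,
    params: FreezingParams = FreezingParams(),
    schedule: EventSchedule | None = None,
) -> pd.DataFrame:
    """Percent time freezing per schedule interval.

    Returns a frame with columns ``label``, ``n_frames``, ``freezing_pct``.
    Without a schedule, a single row labeled ``all`` covers the whole trace.
    """
    if params.min_freeze_frames != round(motion.frame_rate):
        warnings.warn(
            "min_freeze_frames is a frame count, not a duration: "
            f"{params.min_freeze_frames} frames at {motion.frame_rate} fps "
            f"= {params.min_freeze_frames / motion.frame_rate:.2f} s of immobility",
            stacklevel=2,
        )
    mask = freezing_mask(motion, params)
    if schedule is None:
        pct = 100.0 * mask.mean() if mask.size else 0.0
        return pd.DataFrame(
            {"label": ["all"], "n_frames": [mask.size], "freezing_pct": [pct]}
        )
    fps = motion.frame_rate
    rows = []
    for iv in schedule:
        i0 = int(round(iv.start_s * fps))
        n = int(np.floor(iv.duration_s * fps + 1e-9))
        if i0 < 0 or i0 + n > motion.n_frames:
            raise ValidationError(f"interval {iv.label} outside motion trace span")
        sub = mask[i0 : i0 + n]
        rows.append((iv.label, n, 100.0 * sub.mean() if n else 0.0))
    return pd.DataFrame(rows, columns=["label", "n_frames", "freezing_pct"])


def block_means(per_trial: np.ndarray, block_size: int = 5) -> np.ndarray:
    """Mean freezing over consecutive trial blocks (5-trial blocks by default).

    A trailing partial block raises a warning and is averaged over the
    trials it contains.
    """
    per_trial = np.asarray(per_trial, dtype=np.float64)
    if block_size < 1:
        raise ValidationError("block_size must be >= 1")
    n = per_trial.shape[0]
    n_full, rem = divmod(n, block_size)
    means = per_trial[: n_full * block_size].reshape(n_full, block_size).mean(axis=1)
    if rem:
        warnings.warn(
            f"{n} trials not divisible by block size {block_size}; "
            f"trailing block averages {rem} trials",
            stacklevel=2,
        )
        means = np.append(means, per_trial[n_full * block_size :].mean())
    return means


@dataclass(frozen=True)
class Trajectory:
    """Open-field trajectory: timestamps (s) and x, y positions (cm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_side_cm: float = 50.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        x = np.asarray(self.x, dtype=np.float64)
        y = np.asarray(self.y, dtype=np.float64)
        for name, arr in (("t", t), ("x", x), ("y", y)):
            object.__setattr__(self, name, arr)
        if not (t.shape == x.shape == y.shape):
            raise ValidationError("t, x, y must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        side = self.arena_side_cm
        if np.any(x < 0) or np.any(x > side) or np.any(y < 0) or np.any(y > side):
            raise ValidationError("trajectory leaves the arena")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arena_side_cm: float = 50.0) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), arena_side_cm)


def openfield_metrics(
    traj: Trajectory,
    inner_area_cm2: float = 900.0,
    immobility_speed_cms: float = 1.0,
) -> dict[str, float]:
    """Locomotion and center/periphery occupancy metrics.

    The center zone is a concentric square of area ``inner_area_cm2``
    (side sqrt(area)) in the middle of the arena; the periphery is the rest
    of the arena.  A crossing is an entry event into the center zone.
    Time in a zone is accrued per inter-sample step, attributed to the
    zone of the sample starting the step.
    """
    side = np.sqrt(inner_area_cm2)
    lo = (traj.arena_side_cm - side) / 2.0
    hi = lo + side
    in_center = (traj.x >= lo) & (traj.x <= hi) & (traj.y >= lo) & (traj.y <= hi)

    dt = np.diff(traj.t)
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    total_time = traj.t[-1] - traj.t[0]
    distance = float(steps.sum())
    speed = steps / dt
    center_time = float(dt[in_center[:-1]].sum())
    crossings = int(np.sum(in_center[1:] & ~in_center[:-1]))
    immobile_time = float(dt[speed < immobility_speed_cms].sum())
    return {
        "distance_cm": distance,
        "mean_speed_cms": distance / total_time if total_time > 0 else 0.0,
        "time_in_center_frac": center_time / total_time if total_time > 0 else 0.0,
        "time_in_periphery_frac": 1.0 - center_time / total_time if total_time > 0 else 0.0,
        "center_crossings": crossings,
        "immobility_time_s": immobile_time,
    }


def preference_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object preference: t_novel / (t_novel + t_familiar)."""
    if t_novel < 0 or t_familiar < 0:
        raise ValidationError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total == 0:
        raise ValidationError("preference index undefined: no exploration time")
    return t_novel / total
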