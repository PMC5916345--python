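"""Frame schedules and time-activity curves.

Dynamic PET data are acquired as a sequence of contiguous time frames; a
time-activity curve (TAC) is the activity concentration of a region (or
voxel) averaged over each frame.  Frame times are in minutes, activities in
kBq/mL on an arbitrary scale — every model in this package is invariant to
a common rescaling of tissue and reference activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "make_frame_schedule",
    "FMT_BLOCKS",
    "RAC_BLOCKS",
]

# acquisition blocks as (n_frames, duration_min)
FMT_BLOCKS = ((5, 1.0), (3, 2.0), (3, 3.0), (14, 5.0))   # 25 frames, 0-90 min
RAC_BLOCKS = ((5, 1.0), (3, 2.0), (3, 3.0), (8, 5.0))    # 19 frames, 0-60 min


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames.

    Parameters
    ----------
    frame_starts : array-like
        Frame start times in minutes, beginning at 0.
    frame_durations : array-like
        Frame durations in minutes, all positive.
    """

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        if starts.ndim != 1 or starts.shape != durs.shape:
            raise ValueError("frame_starts and frame_durations must be 1-D and equal length")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1], atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)

    @classmethod
    def from_blocks(cls, blocks) -> "FrameSchedule":
        """Build a schedule from ``((n, duration), ...)`` acquisition blocks."""
        durs = np.concatenate([np.full(n, d, dtype=float) for n, d in blocks])
        starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
        return cls(starts, durs)

    @property
    def n_frames(self) -> int:
        return self.frame_starts.size

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2.0

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1])

    def __eq__(self, other):
        if not isinstance(other, FrameSchedule):
            return NotImplemented
        return (self.frame_starts.shape == other.frame_starts.shape
                and np.allclose(self.frame_starts, other.frame_starts)
                and np.allclose(self.frame_durations, other.frame_durations))


def make_frame_schedule(tracer_tag: str) -> FrameSchedule:
    """Return the acquisition schedule for a tracer.

    ``"FMT"`` — 25 frames (5x1, 3x2, 3x3, 14x5 min) spanning 0–90 min, for
    the irreversible synthesis-capacity tracer.  ``"RAC"`` — 19 frames
    (5x1, 3x2, 3x3, 8x5 min) spanning 0–60 min, for the reversible D2/3
    tracer.
    """
    tag = tracer_tag.upper()
    if tag == "FMT":
        return FrameSchedule.from_blocks(FMT_BLOCKS)
    if tag == "RAC":
        return FrameSchedule.from_blocks(RAC_BLOCKS)
    raise ValueError(f"unknown tracer tag {tracer_tag!r}; expected 'FMT' or 'RAC'")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration per frame for one region or voxel."""

    schedule: FrameSchedule
    activity: np.ndarray = field(repr=False)

    def __post_init__(self):
        act = np.asarray(self.activity, dtype=float)
        if act.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"activity has {act.size} values for {self.schedule.n_frames} frames")
        if not np.all(np.isfinite(act)):
            raise ValueError("activity must be finite")
        object.__setattr__(self, "activity", act)

    @property
    def midpoints(self) -> np.ndarray:
        return self.schedule.midpoints

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.activity * factor)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_start_min": self.schedule.frame_starts,
            "frame_duration_min": self.schedule.frame_durations,
            "activity": self.activity,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        sched = FrameSchedule(df["frame_start_min"].to_numpy(),
                              df["frame_duration_min"].to_numpy())
        return cls(sched, df["activity"].to_numpy())
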