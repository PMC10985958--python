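"""Dynamic-PET acquisition frame schedules.

A frame schedule is an ordered, contiguous list of ``(start_s, duration_s)``
acquisition frames.  The default schedule is the 45-frame, 60-minute protocol
used throughout this package: 18 x 10 s, 4 x 30 s, 15 x 60 s and 8 x 300 s,
starting at injection (t = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["FrameSchedule", "default_schedule", "frame_midpoints"]


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered acquisition frames covering a dynamic scan.

    Parameters
    ----------
    frames
        Tuple of ``(start_s, duration_s)`` pairs.  Starts must be strictly
        increasing, durations positive, and frames contiguous
        (``start[i+1] == start[i] + duration[i]``).
    """

    frames: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.frames) == 0:
            raise ValueError("schedule must contain at least one frame")
        starts = np.array([f[0] for f in self.frames], dtype=float)
        durs = np.array([f[1] for f in self.frames], dtype=float)
        if not np.all(np.isfinite(starts)) or not np.all(np.isfinite(durs)):
            raise ValueError("frame starts/durations must be finite")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        if not np.allclose(starts[1:], starts[:-1] + durs[:-1]):
            raise ValueError("frames must be contiguous")

    # -- derived views -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def starts_s(self) -> np.ndarray:
        return np.array([f[0] for f in self.frames], dtype=float)

    @property
    def durations_s(self) -> np.ndarray:
        return np.array([f[1] for f in self.frames], dtype=float)

    @property
    def midpoints_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def end_s(self) -> float:
        start, dur = self.frames[-1]
        return float(start + dur)

    @property
    def span_s(self) -> float:
        """Total covered time from the first frame start to the last end."""
        return self.end_s - float(self.frames[0][0])

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"frames": [[s, d] for s, d in self.frames]}, fh)

    @classmethod
    def from_json(cls, path) -> "FrameSchedule":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(tuple((float(s), float(d)) for s, d in obj["frames"]))


def default_schedule() -> FrameSchedule:
    """The 45-frame, 0-3600 s acquisition: 18x10 s, 4x30 s, 15x60 s, 8x300 s."""
    frames: list[tuple[float, float]] = []
    t = 0.0
    for n, dur in ((18, 10.0), (4, 30.0), (15, 60.0), (8, 300.0)):
        for _ in range(n):
            frames.append((t, dur))
            t += dur
    return FrameSchedule(tuple(frames))


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Midpoint time of each frame, ``start + duration/2`` (seconds)."""
    return schedule.midpoints_s
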