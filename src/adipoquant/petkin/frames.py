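"""Dynamic PET frame schedules, time-activity curves and decay correction."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

#: F-18 physical half-life in minutes.
F18_HALF_LIFE_MIN = 109.77


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous histogramming of an acquisition into frames.

    ``start_s[i+1] == start_s[i] + duration_s[i]`` for all i; the first frame
    starts at injection (t = 0) unless constructed otherwise.
    """

    start_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_s", np.asarray(self.start_s, dtype=float))
        object.__setattr__(self, "duration_s", np.asarray(self.duration_s, dtype=float))
        if self.start_s.shape != self.duration_s.shape or self.start_s.ndim != 1:
            raise ValueError("start_s and duration_s must be 1-D and equal length")
        if len(self.start_s) == 0:
            raise ValueError("schedule must contain at least one frame")
        if np.any(self.duration_s <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(self.start_s[1:], self.start_s[:-1] + self.duration_s[:-1]):
            raise ValueError("frames must be contiguous (start[i+1] = start[i] + duration[i])")

    @property
    def n_frames(self) -> int:
        return len(self.start_s)

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return (self.start_s + self.duration_s / 2.0) / 60.0

    @property
    def total_s(self) -> float:
        return float(self.end_s[-1] - self.start_s[0])


#: The abdominal dynamic acquisition pattern: 12 x 10 s, 4 x 120 s, 10 x 300 s
#: = 26 frames covering 60 min.
DEFAULT_DYNAMIC_PATTERN: tuple[tuple[int, float], ...] = ((12, 10.0), (4, 120.0), (10, 300.0))


def build_frame_schedule(
    pattern: Sequence[tuple[int, float]] = DEFAULT_DYNAMIC_PATTERN,
) -> FrameSchedule:
    """Expand a ``(count, duration_s)`` pattern into a contiguous schedule.

    >>> sched = build_frame_schedule([(12, 10), (4, 120), (10, 300)])
    >>> sched.n_frames, sched.total_s
    (26, 3600.0)
    """
    if len(pattern) == 0:
        raise ValueError("frame pattern must not be empty")
    durations = []
    for count, dur in pattern:
        if count <= 0 or dur <= 0:
            raise ValueError(f"counts and durations must be positive, got ({count}, {dur})")
        durations.extend([float(dur)] * int(count))
    durations = np.array(durations)
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass
class TimeActivityCurve:
    """Per-frame mean activity of a VOI.

    ``decay_corrected_to`` is the reference time of the decay correction
    (``0.0`` = corrected to scan start, the convention used throughout) or
    ``None`` when the activities are raw (uncorrected).
    """

    schedule: FrameSchedule
    activity_kBq_per_ml: np.ndarray
    decay_corrected_to: float | None = 0.0

    def __post_init__(self) -> None:
        self.activity_kBq_per_ml = np.asarray(self.activity_kBq_per_ml, dtype=float)
        if self.activity_kBq_per_ml.shape != self.schedule.start_s.shape:
            raise ValueError("activity length must match the number of frames")

    @property
    def mid_min(self) -> np.ndarray:
        return self.schedule.mid_min


def decay_correct(
    tac: TimeActivityCurve,
    half_life_min: float = F18_HALF_LIFE_MIN,
    direction: Literal["apply", "remove"] = "apply",
) -> TimeActivityCurve:
    """Rescale frame activities to (or from) the scan-start reference.

    Applying multiplies each frame by ``exp(lambda * t_mid)`` with
    ``lambda = ln 2 / half_life`` and ``t_mid`` the frame midpoint, undoing
    physical decay since injection; removing divides it back out.
    ``apply`` on an already-corrected curve (or ``remove`` on a raw one) is
    rejected via the ``decay_corrected_to`` flag so the correction cannot be
    stacked silently.
    """
    lam = np.log(2.0) / half_life_min
    factor = np.exp(lam * tac.mid_min)
    if direction == "apply":
        if tac.decay_corrected_to is not None:
            raise ValueError("TAC is already decay-corrected; refusing to apply twice")
        return TimeActivityCurve(tac.schedule, tac.activity_kBq_per_ml * factor, 0.0)
    if direction == "remove":
        if tac.decay_corrected_to is None:
            raise ValueError("TAC is not decay-corrected; nothing to remove")
        return TimeActivityCurve(tac.schedule, tac.activity_kBq_per_ml / factor, None)
    raise ValueError(f"direction must be 'apply' or 'remove', got {direction!r}")
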