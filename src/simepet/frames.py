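"""Frame schedules and regional time-activity curves.

Dynamic PET data are reported as frame-averaged radioactivity concentrations.
A :class:`FrameSchedule` stores the frame boundaries (in seconds, as scanners
report them); a :class:`TimeActivityCurve` binds one region's decay-corrected
activity (kBq/ml) to such a schedule.  All model arithmetic elsewhere in the
package uses minutes; conversion happens at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyResultError, InvalidParameterError

__all__ = ["FrameSchedule", "TimeActivityCurve", "make_frame_schedule", "FRAME_PRESETS"]


@dataclass(frozen=True)
class FrameSchedule:
    """Frame boundaries of a dynamic PET acquisition.

    Parameters
    ----------
    frame_start, frame_end : array-like of float
        Frame start/end times in **seconds** post-injection.  Starts must be
        strictly increasing, each frame must have positive duration, and
        frames may not overlap (gaps are allowed).
    label : str
        Free-text identifier, e.g. ``"hrrt_120"`` or ``"mmr_90"``.
    """

    frame_start: np.ndarray
    frame_end: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        end = np.asarray(self.frame_end, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_end", end)
        if start.ndim != 1 or start.shape != end.shape or start.size == 0:
            raise InvalidParameterError("frame_start/frame_end must be equal-length 1-D arrays")
        if not (np.isfinite(start).all() and np.isfinite(end).all()):
            raise InvalidParameterError("frame times must be finite")
        if (start < 0).any():
            raise InvalidParameterError("frame_start must be >= 0")
        if not (end > start).all():
            raise InvalidParameterError("every frame must satisfy frame_end > frame_start")
        if start.size > 1:
            if not (np.diff(start) > 0).all():
                raise InvalidParameterError("frame starts must be strictly increasing")
            if not (start[1:] >= end[:-1]).all():
                raise InvalidParameterError("frames must not overlap")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def duration_s(self) -> np.ndarray:
        """Per-frame duration in seconds."""
        return self.frame_end - self.frame_start

    @property
    def start_min(self) -> np.ndarray:
        return self.frame_start / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.frame_end / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        """Frame midpoints in minutes."""
        return 0.5 * (self.frame_start + self.frame_end) / 60.0

    @property
    def total_end_min(self) -> float:
        return float(self.frame_end[-1] / 60.0)

    def truncated(self, duration_min: float) -> "FrameSchedule":
        """Keep frames wholly inside ``[0, duration_min]`` (frame_end <= duration)."""
        if duration_min <= 0:
            raise InvalidParameterError("truncation duration must be > 0")
        keep = self.frame_end <= duration_min * 60.0 + 1e-9
        if not keep.any():
            raise EmptyResultError(
                f"truncation to {duration_min} min leaves no complete frame"
            )
        return FrameSchedule(self.frame_start[keep], self.frame_end[keep], self.label)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-averaged regional activity bound to a frame schedule.

    ``activity`` is decay-corrected radioactivity concentration in kBq/ml,
    one value per frame.  Negative values are permitted (measured noise can
    undershoot zero) but every value must be finite.
    """

    region: str
    schedule: FrameSchedule
    activity: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "activity", act)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise InvalidParameterError(
                f"activity length {act.size} does not match schedule "
                f"({self.schedule.n_frames} frames)"
            )
        if not np.isfinite(act).all():
            raise InvalidParameterError("TAC activity must be finite")

    def truncated(self, duration_min: float) -> "TimeActivityCurve":
        """Drop frames ending after ``duration_min`` minutes."""
        sched = self.schedule.truncated(duration_min)
        return TimeActivityCurve(self.region, sched, self.activity[: sched.n_frames])


def _expand(recipe: list[tuple[int, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Turn a (count, duration_s) recipe into start/end arrays."""
    durations = np.concatenate([np.full(n, d, dtype=float) for n, d in recipe])
    end = np.cumsum(durations)
    start = end - durations
    return start, end


# Scanner acquisition recipes.  The HRRT protocols are preceded in the raw
# data by one background frame of variable length, which carries no tracer
# signal and is excluded here.
FRAME_PRESETS: dict[str, list[tuple[int, float]]] = {
    # 33 frames, nominal 120-min HRRT acquisition
    "hrrt_120": [(5, 30), (1, 45), (2, 60), (1, 90), (1, 120), (1, 210), (22, 300)],
    # 44 frames, nominal 180-min HRRT acquisition
    "hrrt_180": [(5, 30), (1, 45), (2, 60), (1, 90), (1, 120), (1, 210), (33, 300)],
    # 52 frames, 90-min PET/MR (mMR) acquisition; totals 5399 s
    "mmr_90": [
        (1, 20), (12, 5), (8, 15), (4, 30), (5, 60), (10, 120), (11, 300), (1, 279)
    ],
}


def make_frame_schedule(preset: str) -> FrameSchedule:
    """Return one of the scanner frame-schedule presets.

    ``hrrt_120`` (33 frames), ``hrrt_180`` (44 frames) and ``mmr_90``
    (52 frames, 5399 s total) reproduce the standard acquisition protocols.
    """
    try:
        recipe = FRAME_PRESETS[preset]
    except KeyError:
        raise InvalidParameterError(
            f"unknown frame-schedule preset {preset!r}; "
            f"choose from {sorted(FRAME_PRESETS)}"
        ) from None
    start, end = _expand(recipe)
    return FrameSchedule(start, end, label=preset)
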