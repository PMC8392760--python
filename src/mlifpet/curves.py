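"""Time-activity curves, frame schedules, resampling and windowing.

These are the shared currency of the whole pipeline: every stage (blood
processing, carotid segmentation, GP prediction, kinetic modelling)
consumes and produces :class:`TimeActivityCurve` objects, either on the
scanner's frame grid or on a uniform 1-s grid.  Internal units are
seconds and kBq/mL throughout; unit conversions happen only at I/O
boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "default_frame_schedule",
    "resample_to_1s",
    "window_curve",
    "window_0_to_6min",
    "rebin_to_frames",
    "DEFAULT_WINDOW_S",
]

#: Analysis window end point: curves are cut to t in [0, 360] s (0-6 min)
#: to avoid the noisy late part of a 10-min water scan.
DEFAULT_WINDOW_S = 360.0


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous dynamic-PET frame timing in seconds.

    ``frame_start[i+1] == frame_start[i] + frame_duration[i]`` and the
    first frame starts at injection (t = 0).
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("frame_start and frame_duration must be 1-D and equal length")
        if not np.all(dur > 0):
            raise ValueError("frame durations must be positive")
        if start[0] != 0:
            raise ValueError("first frame must start at t = 0")
        if not np.allclose(start[1:], start[:-1] + dur[:-1]):
            raise ValueError("frames must be contiguous")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def total_duration(self) -> float:
        return float(self.frame_start[-1] + self.frame_duration[-1])

    @property
    def frame_mid(self) -> np.ndarray:
        """Frame midpoints, the nominal sample times of a frame-based TAC."""
        return self.frame_start + self.frame_duration / 2.0

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @classmethod
    def from_durations(cls, durations) -> "FrameSchedule":
        dur = np.asarray(durations, dtype=float)
        start = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
        return cls(start, dur)

    def to_dict(self) -> dict:
        return {
            "frame_start_s": self.frame_start.tolist(),
            "frame_duration_s": self.frame_duration.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FrameSchedule":
        return cls(np.asarray(d["frame_start_s"]), np.asarray(d["frame_duration_s"]))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) sampled over time (s).

    ``grid_kind`` distinguishes scanner frame-based sampling (t are frame
    midpoints) from the uniform 1-s grid used for blood data and kinetic
    modelling.
    """

    t: np.ndarray
    value: np.ndarray
    grid_kind: str = "frame-based"  # "frame-based" | "uniform-1s"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "value", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("t and value must be 1-D arrays of equal length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("t must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("curve values must be finite")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Grid spacing; only meaningful for uniform grids."""
        if len(self.t) < 2:
            raise ValueError("need at least two samples to infer dt")
        steps = np.diff(self.t)
        if not np.allclose(steps, steps[0]):
            raise ValueError("curve is not on a uniform grid")
        return float(steps[0])

    @property
    def peak(self) -> float:
        return float(np.max(self.value))

    def with_values(self, value: np.ndarray) -> "TimeActivityCurve":
        return TimeActivityCurve(self.t, np.asarray(value, dtype=float), self.grid_kind)


def default_frame_schedule() -> FrameSchedule:
    """The 26-frame, 10-min dynamic water-scan framing.

    1x10, 8x5, 4x10, 2x15, 3x20, 2x30 and 6x60 s frames, totalling 600 s.
    """
    durations = [10.0] + [5.0] * 8 + [10.0] * 4 + [15.0] * 2 + [20.0] * 3 + [30.0] * 2 + [60.0] * 6
    return FrameSchedule.from_durations(durations)


def resample_to_1s(tac: TimeActivityCurve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Linearly interpolate a frame-based TAC onto a uniform 1-s grid.

    Frame values are placed at frame midpoints.  Before the first
    midpoint the curve is linearly extrapolated from 0 at t = 0 (scans
    start at injection, so there is no pre-injection activity); after
    the last midpoint the last value is held.
    """
    if len(tac) != schedule.n_frames:
        raise ValueError(
            f"curve has {len(tac)} samples but schedule has {schedule.n_frames} frames"
        )
    grid = np.arange(0.0, np.floor(schedule.total_duration) + 1.0)
    knots_t = np.concatenate([[0.0], schedule.frame_mid])
    # linear ramp from zero at injection to the first frame value
    knots_v = np.concatenate([[0.0], tac.value])
    out = np.interp(grid, knots_t, knots_v)
    return TimeActivityCurve(grid, out, grid_kind="uniform-1s")


def window_curve(tac: TimeActivityCurve, t_max: float = DEFAULT_WINDOW_S) -> TimeActivityCurve:
    """Keep samples with t <= t_max (closed interval, 361 samples at 1 Hz)."""
    if tac.t[-1] < t_max:
        raise ValueError(f"curve ends at {tac.t[-1]} s, shorter than the {t_max} s window")
    keep = tac.t <= t_max
    return TimeActivityCurve(tac.t[keep], tac.value[keep], tac.grid_kind)


def window_0_to_6min(tac: TimeActivityCurve) -> TimeActivityCurve:
    """Restrict a uniform 1-s curve to the 0-6 min analysis window."""
    return window_curve(tac, DEFAULT_WINDOW_S)


def rebin_to_frames(tac: TimeActivityCurve, schedule: FrameSchedule) -> TimeActivityCurve:
    """Average a uniform 1-s curve back onto the scanner frame grid.

    Only frames fully covered by the curve's support are kept, so a
    0-360 s curve maps onto the first 22 frames of the default schedule.
    Used for point-by-point curve comparisons on the original framing.
    """
    dt = tac.dt
    mids, vals = [], []
    for start, dur, mid in zip(schedule.frame_start, schedule.frame_duration, schedule.frame_mid):
        sel = (tac.t >= start) & (tac.t < start + dur)
        if start + dur - dt > tac.t[-1] or not np.any(sel):
            break
        mids.append(mid)
        vals.append(float(np.mean(tac.value[sel])))
    return TimeActivityCurve(np.asarray(mids), np.asarray(vals), grid_kind="frame-based")
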