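"""Core containers shared by every stage of the pipeline.

Units are fixed package-wide: time in minutes, activity concentration in
kBq/mL (or any consistent multiple — the quantitative endpoints V_T and SUV
are invariant to a common rescaling of tissue and blood), injected dose in
MBq, body weight in grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import CoverageError, ValidationError

#: Physical half-life of fluorine-18 in minutes.
F18_HALF_LIFE_MIN = 109.8


@dataclass(frozen=True)
class FrameSchedule:
    """Ordered, contiguous acquisition frames.

    Frames are half-open intervals ``[start, start + duration)`` in minutes,
    starting at zero. Model curves are averaged over frames; Logan abscissae
    use frame midpoints.
    """

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)
        if starts.ndim != 1 or starts.shape != durations.shape or starts.size == 0:
            raise ValidationError("starts and durations must be equal-length 1-D arrays")
        if starts[0] != 0.0:
            raise ValidationError("first frame must start at t = 0")
        if np.any(durations <= 0):
            raise ValidationError("all frame durations must be positive")
        gaps = starts[1:] - (starts[:-1] + durations[:-1])
        if np.any(np.abs(gaps) > 1e-9):
            bad = int(np.argmax(np.abs(gaps) > 1e-9)) + 1
            raise ValidationError(f"frames are not contiguous at frame index {bad}")

    @classmethod
    def from_durations(cls, durations_min) -> "FrameSchedule":
        durations = np.asarray(durations_min, dtype=float)
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)

    @classmethod
    def from_groups(cls, groups_sec) -> "FrameSchedule":
        """Build from ``(count, frame_seconds)`` groups, e.g. ``[(12, 10), ...]``."""
        durations = np.concatenate(
            [np.full(int(n), float(sec) / 60.0) for n, sec in groups_sec]
        )
        return cls.from_durations(durations)

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + 0.5 * self.durations

    @property
    def total_duration(self) -> float:
        return float(self.ends[-1])

    def truncated(self, duration_min: float) -> "FrameSchedule":
        """Frames fully contained in ``[0, duration_min]``."""
        keep = self.ends <= duration_min + 1e-9
        if not np.any(keep):
            raise ValidationError("truncation removes every frame")
        return FrameSchedule(self.starts[keep], self.durations[keep])

    def __eq__(self, other):
        # tolerant to last-ulp differences from file round trips
        return (
            isinstance(other, FrameSchedule)
            and self.starts.shape == other.starts.shape
            and np.allclose(self.starts, other.starts, atol=1e-9)
            and np.allclose(self.durations, other.durations, atol=1e-9)
        )


def make_standard_frame_schedule() -> FrameSchedule:
    """The 120-min dynamic mouse acquisition schedule used throughout.

    45 frames of increasing duration: 12 x 10 s, 3 x 20 s, 3 x 30 s,
    3 x 60 s, 3 x 150 s and 21 x 300 s, totalling exactly 7200 s.
    """
    return FrameSchedule.from_groups(
        [(12, 10), (3, 20), (3, 30), (3, 60), (3, 150), (21, 300)]
    )


@dataclass
class InputFunction:
    """Whole-blood and metabolite-corrected plasma-parent curves on a
    uniform fine time grid starting at t = 0."""

    times: np.ndarray
    whole_blood: np.ndarray
    plasma_parent: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        wb = np.asarray(self.whole_blood, dtype=float)
        pp = np.asarray(self.plasma_parent, dtype=float)
        if not (t.shape == wb.shape == pp.shape) or t.ndim != 1 or t.size < 2:
            raise ValidationError("times/whole_blood/plasma_parent must be equal-length 1-D arrays")
        steps = np.diff(t)
        if t[0] != 0.0 or np.any(steps <= 0) or np.ptp(steps) > 1e-9 * steps[0]:
            raise ValidationError("times must be a uniform grid starting at 0")
        if np.any(wb < 0) or np.any(pp < 0):
            raise ValidationError("input-function activities must be nonnegative")
        self.times, self.whole_blood, self.plasma_parent = t, wb, pp

    @property
    def grid_step(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def require_coverage(self, t_end: float) -> None:
        if t_end > self.t_end + 1e-9:
            raise CoverageError(
                f"schedule extends to {t_end:g} min but input grid ends at {self.t_end:g} min"
            )

    def cumulative_plasma_integral(self) -> np.ndarray:
        """Running trapezoid integral of the plasma-parent curve on the grid."""
        return cumulative_trapezoid(self.plasma_parent, self.times, initial=0.0)


@dataclass
class TacTable:
    """Frame-averaged regional activity concentrations for one scan."""

    schedule: FrameSchedule
    values: pd.DataFrame  # one column per region, one row per frame

    def __post_init__(self):
        if len(self.values) != self.schedule.n_frames:
            raise ValidationError(
                f"TAC table has {len(self.values)} rows for {self.schedule.n_frames} frames"
            )
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("TAC values must be finite")
        self.values = self.values.astype(float).reset_index(drop=True)

    @property
    def regions(self) -> list:
        return list(self.values.columns)

    def region(self, name: str | None = None) -> np.ndarray:
        """Frame values for one region; ``None`` allowed when there is only one."""
        if name is None:
            if len(self.values.columns) != 1:
                raise ValidationError("region name required for a multi-region table")
            name = self.values.columns[0]
        return self.values[name].to_numpy()

    @property
    def has_negative(self) -> bool:
        """Negative frame values are permitted (noise) but worth flagging."""
        return bool((self.values.to_numpy() < 0).any())

    def truncated(self, duration_min: float) -> "TacTable":
        sched = self.schedule.truncated(duration_min)
        return TacTable(sched, self.values.iloc[: sched.n_frames].copy())

    def drop_region(self, name: str) -> "TacTable":
        return TacTable(self.schedule, self.values.drop(columns=[name]))
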