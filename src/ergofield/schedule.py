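"""Work-shift schedule: clock arithmetic shared by every pipeline stage.

All times are integer seconds-of-day; every window is half-open ``[start, end)``
so that boundary samples are never double-counted between adjacent windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PERIODS = ("T0", "T1", "T2", "T3")

#: survey-aligned heart-rate window durations, seconds (T0 is the 15-min
#: pre-shift quiet-sitting measurement; T1-T3 are 10 min each)
HR_WINDOW_SECONDS = {"T0": 900, "T1": 600, "T2": 600, "T3": 600}


class ScheduleError(ValueError):
    """Raised for schedules that violate shift/break/window ordering."""


def parse_clock(text: str | int | float) -> int:
    """Convert ``"H:MM"`` / ``"H:MM:SS"`` (or a number of seconds) to seconds-of-day."""
    if isinstance(text, (int, float, np.integer, np.floating)):
        return int(text)
    parts = text.strip().split(":")
    if not 2 <= len(parts) <= 3:
        raise ScheduleError(f"cannot parse clock time {text!r}")
    h, m = int(parts[0]), int(parts[1])
    s = int(parts[2]) if len(parts) == 3 else 0
    return h * 3600 + m * 60 + s


def format_clock(seconds: int) -> str:
    h, rem = divmod(int(seconds), 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}" if s else f"{h:02d}:{m:02d}"


@dataclass(frozen=True)
class ShiftSchedule:
    """A work shift with one mid-shift break and survey-aligned HR windows.

    Parameters
    ----------
    shift_start, shift_end, break_start, break_end:
        Seconds-of-day. Must satisfy
        ``shift_start < break_start < break_end < shift_end``.
    survey_times:
        Clock time at which each of the T0-T3 effort surveys is administered.
    hr_windows:
        Half-open ``[start, end)`` intervals over which period heart-rate
        means are taken. T0 is pre-shift sitting; T1 and T3 cover the last
        10 min of the work bout preceding the respective survey; T2 starts
        right after the break.
    """

    shift_start: int
    shift_end: int
    break_start: int
    break_end: int
    survey_times: dict[str, int] = field(default_factory=dict)
    hr_windows: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.shift_start < self.break_start < self.break_end < self.shift_end):
            raise ScheduleError(
                "require shift_start < break_start < break_end < shift_end, got "
                f"{format_clock(self.shift_start)} / {format_clock(self.break_start)}"
                f" / {format_clock(self.break_end)} / {format_clock(self.shift_end)}"
            )
        if set(self.survey_times) != set(PERIODS):
            raise ScheduleError(f"survey_times must define exactly {PERIODS}")
        if set(self.hr_windows) != set(PERIODS):
            raise ScheduleError(f"hr_windows must define exactly {PERIODS}")
        for period, (lo, hi) in self.hr_windows.items():
            if hi - lo != HR_WINDOW_SECONDS[period]:
                raise ScheduleError(
                    f"{period} HR window must last {HR_WINDOW_SECONDS[period]} s, "
                    f"got {hi - lo}"
                )
            if lo < self.recording_start or hi > self.shift_end:
                raise ScheduleError(f"{period} HR window outside the recording span")
        for period in ("T1", "T3"):
            lo, hi = self.hr_windows[period]
            if not self._interval_in_work(lo, hi):
                raise ScheduleError(f"{period} HR window must lie inside a work bout")

    # -- derived geometry ---------------------------------------------------

    @property
    def recording_start(self) -> int:
        """Start of the pre-shift sitting measurement (earliest HR sample)."""
        return min(self.hr_windows["T0"][0], self.shift_start)

    @property
    def work_intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.shift_start, self.break_start),
            (self.break_end, self.shift_end),
        )

    def _interval_in_work(self, lo: int, hi: int) -> bool:
        return any(lo >= a and hi <= b for a, b in self.work_intervals)

    def in_break(self, t: np.ndarray | int) -> np.ndarray | bool:
        t = np.asarray(t)
        out = (t >= self.break_start) & (t < self.break_end)
        return out if out.ndim else bool(out)

    def in_work(self, t: np.ndarray | int) -> np.ndarray | bool:
        t = np.asarray(t)
        out = ((t >= self.shift_start) & (t < self.break_start)) | (
            (t >= self.break_end) & (t < self.shift_end)
        )
        return out if out.ndim else bool(out)

    def work_seconds_elapsed(self, t: np.ndarray | int) -> np.ndarray | float:
        """Cumulative seconds of *work* completed at clock time ``t``.

        Frozen during the break, so a quantity that drifts with work time
        (e.g. the programmed EMG spectral center) holds its pre-break value
        until work resumes.
        """
        t = np.asarray(t, dtype=float)
        morning = np.clip(t - self.shift_start, 0.0, self.break_start - self.shift_start)
        afternoon = np.clip(t - self.break_end, 0.0, self.shift_end - self.break_end)
        out = morning + afternoon
        return out if out.ndim else float(out)

    def work_minutes_elapsed(self, t: np.ndarray | int) -> np.ndarray | float:
        out = np.asarray(self.work_seconds_elapsed(t)) / 60.0
        return out if out.ndim else float(out)

    @property
    def total_work_minutes(self) -> float:
        return sum(b - a for a, b in self.work_intervals) / 60.0

    # -- constructors -------------------------------------------------------

    @classmethod
    def standard(cls, break_minutes: int = 30) -> "ShiftSchedule":
        """The full-day apple-harvest schedule: 7:30-15:00 with a mid-morning break.

        ``break_minutes`` selects between the 30-min-rest layout (default, the
        one the survey timeline describes) and the 90-min 9:00-10:30 variant.
        """
        return cls.from_times("7:30", "15:00", "9:00", break_minutes=break_minutes)

    @classmethod
    def smoke(cls) -> "ShiftSchedule":
        """A compressed 70-min shift used for fast end-to-end runs."""
        return cls.from_times("7:30", "8:40", "8:00", break_minutes=10)

    @classmethod
    def from_times(
        cls,
        shift_start: str | int,
        shift_end: str | int,
        break_start: str | int,
        break_minutes: int = 30,
    ) -> "ShiftSchedule":
        start = parse_clock(shift_start)
        end = parse_clock(shift_end)
        b0 = parse_clock(break_start)
        b1 = b0 + 60 * int(break_minutes)
        hr_windows = {
            "T0": (start - 900, start),
            "T1": (b0 - 600, b0),
            "T2": (b1, b1 + 600),
            "T3": (end - 600, end),
        }
        survey_times = {"T0": start - 900, "T1": b0, "T2": b1, "T3": end}
        return cls(
            shift_start=start,
            shift_end=end,
            break_start=b0,
            break_end=b1,
            survey_times=survey_times,
            hr_windows=hr_windows,
        )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "shift_start": format_clock(self.shift_start),
            "shift_end": format_clock(self.shift_end),
            "break_start": format_clock(self.break_start),
            "break_end": format_clock(self.break_end),
            "survey_times": {k: format_clock(v) for k, v in self.survey_times.items()},
            "hr_windows": {
                k: [format_clock(a), format_clock(b)]
                for k, (a, b) in self.hr_windows.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShiftSchedule":
        return cls(
            shift_start=parse_clock(d["shift_start"]),
            shift_end=parse_clock(d["shift_end"]),
            break_start=parse_clock(d["break_start"]),
            break_end=parse_clock(d["break_end"]),
            survey_times={k: parse_clock(v) for k, v in d["survey_times"].items()},
            hr_windows={
                k: (parse_clock(a), parse_clock(b))
                for k, (a, b) in d["hr_windows"].items()
            },
        )
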