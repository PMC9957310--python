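"""Heart-rate cleaning and the percent heart-rate-reserve metabolic-load metric.

%HRR normalizes the working heart rate by the individual reserve::

    HRmax  = 220 - age
    HRrest = HRsit - 10
    %HRR   = (HRwork - HRrest) / (HRmax - HRrest)

where HRsit is the mean heart rate over the pre-shift quiet-sitting window
and HRwork the mean over a survey-aligned work window, both taken after a
5-point moving-median artifact filter. %HRR is square-root transformed for
normality before parametric modelling; both scales are always emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schedule import ShiftSchedule


class MissingDataError(ValueError):
    """Raised when a requested window contains no usable samples."""


class DomainError(ValueError):
    """Raised when %HRR is undefined (non-positive reserve denominator)."""


@dataclass
class HeartRateSeries:
    """1-Hz heart-rate record: strictly increasing seconds-of-day + bpm."""

    subject_id: str
    time_s: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.int64)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.time_s.shape != self.bpm.shape:
            raise ValueError("time_s and bpm must have equal length")
        if self.time_s.size and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.time_s.size


def moving_median(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving median; edges use the available (shrunken) window.

    The interior is vectorized over a sliding window view; at each boundary
    the window simply shrinks to whatever samples exist, so no data are
    invented beyond the recording edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(values, dtype=float)
    n = x.size
    if window == 1 or n == 0:
        return x.copy()
    half = window // 2
    out = np.empty_like(x)
    if n >= window:
        view = np.lib.stride_tricks.sliding_window_view(x, window)
        out[half : n - half] = np.median(view, axis=1)
    for i in range(min(half, n)):
        out[i] = np.median(x[: i + half + 1])
        out[n - 1 - i] = np.median(x[max(0, n - 1 - i - half) :])
    if n < window:  # tiny series: every position is an edge
        for i in range(n):
            out[i] = np.median(x[max(0, i - half) : i + half + 1])
    return out


def moving_median_filter(series: HeartRateSeries, window: int = 5) -> HeartRateSeries:
    """Apply the artifact-suppressing moving median to a heart-rate series."""
    return HeartRateSeries(
        subject_id=series.subject_id,
        time_s=series.time_s.copy(),
        bpm=moving_median(series.bpm, window),
    )


@dataclass(frozen=True)
class PeriodMean:
    mean_bpm: float
    coverage: float
    low_coverage: bool


def period_mean(
    series: HeartRateSeries,
    window: tuple[int, int],
    *,
    nominal_rate_hz: float = 1.0,
    min_coverage: float = 0.5,
) -> PeriodMean:
    """Mean bpm over the half-open window ``[start, end)`` with a coverage flag.

    Coverage is samples present / samples expected at the nominal rate; means
    over sparse windows are still returned but flagged, and an empty window
    raises rather than silently yielding zero.
    """
    start, end = window
    if end <= start:
        raise MissingDataError(f"degenerate window [{start}, {end})")
    mask = (series.time_s >= start) & (series.time_s < end)
    n = int(mask.sum())
    if n == 0:
        raise MissingDataError(
            f"no heart-rate samples in [{start}, {end}) for {series.subject_id}"
        )
    expected = (end - start) * nominal_rate_hz
    coverage = n / expected
    return PeriodMean(
        mean_bpm=float(series.bpm[mask].mean()),
        coverage=float(coverage),
        low_coverage=coverage < min_coverage,
    )


def compute_hrr(hr_work: float, hr_sit: float, age: float) -> dict:
    """Evaluate the reserve equations for one subject-period.

    Values outside [0, 1] are physiologically possible under the sitting-HR
    approximation and are returned with ``out_of_range=True`` rather than
    clipped; ``hrr_sqrt`` is NaN for negative %HRR.
    """
    hr_max = 220.0 - float(age)
    hr_rest = float(hr_sit) - 10.0
    denom = hr_max - hr_rest
    if denom <= 0:
        raise DomainError(
            f"non-positive heart-rate reserve (HRmax={hr_max}, HRrest={hr_rest})"
        )
    hrr = (float(hr_work) - hr_rest) / denom
    return {
        "hr_work": float(hr_work),
        "hr_sit": float(hr_sit),
        "hr_rest": hr_rest,
        "hr_max": hr_max,
        "hrr": hrr,
        "hrr_sqrt": float(np.sqrt(hrr)) if hrr >= 0 else float("nan"),
        "out_of_range": not 0.0 <= hrr <= 1.0,
    }


def hrr_table(
    heart_rate: dict[str, HeartRateSeries],
    roster: pd.DataFrame,
    schedule: ShiftSchedule,
    *,
    median_window: int = 5,
    min_coverage: float = 0.5,
) -> pd.DataFrame:
    """Per-subject, per-period %HRR results (tidy frame, one row per T1-T3).

    Subjects whose T0 window is empty are reported as missing rows (NaN
    metrics) rather than dropped.
    """
    rows = []
    for _, subj in roster.iterrows():
        series = heart_rate.get(subj.subject_id)
        if series is None:
            continue
        filtered = moving_median_filter(series, median_window)
        try:
            sit = period_mean(
                filtered, schedule.hr_windows["T0"], min_coverage=min_coverage
            )
        except MissingDataError:
            sit = None
        for period in ("T1", "T2", "T3"):
            row = {"subject_id": subj.subject_id, "group": subj.group, "period": period}
            try:
                work = period_mean(
                    filtered, schedule.hr_windows[period], min_coverage=min_coverage
                )
            except MissingDataError:
                work = None
            if sit is None or work is None:
                row.update(
                    hr_work=np.nan, hr_sit=np.nan, hr_rest=np.nan, hr_max=np.nan,
                    hrr=np.nan, hrr_sqrt=np.nan, out_of_range=False,
                    coverage_sit=np.nan if sit is None else sit.coverage,
                    coverage_work=np.nan if work is None else work.coverage,
                    missing=True,
                )
            else:
                row.update(compute_hrr(work.mean_bpm, sit.mean_bpm, subj.age))
                row.update(
                    coverage_sit=sit.coverage,
                    coverage_work=work.coverage,
                    missing=False,
                )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TransformReport:
    """Square-root transform output plus before/after normality diagnostics."""

    transformed: np.ndarray
    n_excluded_negative: int
    shapiro_before: tuple[float, float] | None  # (W, p)
    shapiro_after: tuple[float, float] | None


def sqrt_transform_with_normality(values) -> TransformReport:
    """Square-root transform a %HRR sample and report Shapiro-Wilk both ways.

    Negative values (possible when a work window falls below resting rate)
    are excluded from the transform with a counted warning. With fewer than
    3 finite values the normality tests are unavailable (None) but the
    transform is still returned.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    neg = int((x < 0).sum())
    if neg:
        warnings.warn(f"excluding {neg} negative value(s) from sqrt transform")
        x = x[x >= 0]
    transformed = np.sqrt(x)

    def _shapiro(sample: np.ndarray) -> tuple[float, float] | None:
        if sample.size < 3 or np.ptp(sample) == 0:
            return None
        w = stats.shapiro(sample)
        return (float(w.statistic), float(w.pvalue))

    return TransformReport(
        transformed=transformed,
        n_excluded_negative=neg,
        shapiro_before=_shapiro(x),
        shapiro_after=_shapiro(transformed),
    )
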