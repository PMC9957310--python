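"""Trapezius surface-EMG processing: bandpass, windowed spectral features,
PCA artifact screening, and the median-power-frequency fatigue slope.

The fatigue metric is the median power frequency (MDF) of the 20-450 Hz band,
summarized per 10-min window and regressed on work time::

    MPF = b0 + b_time * time

A negative ``b_time`` (spectral compression) indicates accumulating localized
muscle fatigue. The mean power frequency (MNF) is computed and stored for
every window as well and can be selected as the fatigue metric instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.decomposition import PCA

from .schedule import ShiftSchedule

ANALYSIS_BAND = (20.0, 450.0)

#: window summaries entering the PCA artifact screen
SCREEN_FEATURES = ["amp_p10", "amp_p50", "amp_p90", "mnf", "mdf", "total_power"]


class SpectralError(ValueError):
    """Raised when a spectral summary is undefined (e.g. zero total power)."""


@dataclass
class EmgRecording:
    """One continuous surface-EMG channel (mV) at a fixed sampling rate."""

    subject_id: str
    side: str
    sampling_rate: float
    start_time_s: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 2 * ANALYSIS_BAND[1]:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz below Nyquist for the "
                f"{ANALYSIS_BAND[1]} Hz analysis band"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate


def bandpass(
    recording: EmgRecording,
    low: float = 20.0,
    high: float = 450.0,
    order: int = 4,
) -> EmgRecording:
    """Zero-phase Butterworth bandpass (applied forward-backward).

    Forward-backward application doubles the effective order, giving well
    over 40 dB attenuation one octave beyond either cutoff.
    """
    fs = recording.sampling_rate
    if not 0 < low < high < fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) Hz for fs={fs} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return EmgRecording(
        subject_id=recording.subject_id,
        side=recording.side,
        sampling_rate=fs,
        start_time_s=recording.start_time_s,
        samples=filtered,
    )


def median_power_frequency(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Frequency splitting the in-band power in half.

    The density is integrated with the trapezoid rule and the half-power
    crossing located by linear interpolation of the cumulative integral, so a
    uniform density on [20, 450] gives the band midpoint 235 Hz and a point
    mass gives its own bin.
    """
    f, p = _band_select(freqs, psd, band)
    cum = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2.0 * np.diff(f))])
    total = cum[-1]
    if total <= 0:
        raise SpectralError("zero total power in the analysis band")
    return float(np.interp(total / 2.0, cum, f))


def mean_power_frequency(
    freqs: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Power-weighted average frequency over the analysis band."""
    f, p = _band_select(freqs, psd, band)
    total = np.trapezoid(p, f)
    if total <= 0:
        raise SpectralError("zero total power in the analysis band")
    return float(np.trapezoid(f * p, f) / total)


def _band_select(freqs, psd, band):
    f = np.asarray(freqs, dtype=float)
    p = np.asarray(psd, dtype=float)
    if np.any(p < 0):
        raise SpectralError("power spectral density must be non-negative")
    mask = (f >= band[0]) & (f <= band[1])
    if mask.sum() < 2:
        raise SpectralError("fewer than two PSD bins inside the analysis band")
    return f[mask], p[mask]


def window_features(
    recording: EmgRecording,
    schedule: ShiftSchedule,
    *,
    window_length_s: int = 600,
    min_fraction: float = 0.5,
    band: tuple[float, float] = ANALYSIS_BAND,
    welch_segment_s: float = 1.0,
) -> pd.DataFrame:
    """Per-window amplitude and spectral summaries of a bandpassed recording.

    Consecutive non-overlapping windows start at the shift start. Each carries
    rectified-amplitude percentiles (10/50/90), MNF, MDF, total in-band power,
    the window midpoint both as clock minutes since shift start (``t_mid``)
    and as cumulative work minutes (``t_work``), and an ``in_break`` flag
    (set when more than half the window overlaps the break). The PSD is a
    Welch estimate (1-s Hann segments, 50% overlap: 1-Hz resolution).
    Degenerate windows (zero power) are flagged anomalous with NaN spectral
    features. A trailing fragment shorter than ``min_fraction`` of the window
    is dropped.
    """
    fs = recording.sampling_rate
    n_win = int(window_length_s * fs)
    x = recording.samples
    if x.size < int(min_fraction * n_win):
        warnings.warn(
            f"recording {recording.subject_id}/{recording.side} shorter than the "
            "minimum analysis window; no features computed"
        )
        return _empty_features()
    nperseg = int(welch_segment_s * fs)
    rows = []
    for w_idx, a in enumerate(range(0, x.size, n_win)):
        seg = x[a : a + n_win]
        if seg.size < int(min_fraction * n_win):
            continue
        t0 = recording.start_time_s + a / fs
        t1 = t0 + seg.size / fs
        t_mid_clock = (t0 + t1) / 2.0
        overlap = max(
            0.0, min(t1, schedule.break_end) - max(t0, schedule.break_start)
        )
        rect = np.abs(seg)
        p10, p50, p90 = np.percentile(rect, [10, 50, 90])
        row = {
            "subject_id": recording.subject_id,
            "side": recording.side,
            "window_index": w_idx,
            "t_mid": (t_mid_clock - schedule.shift_start) / 60.0,
            "t_work": float(schedule.work_minutes_elapsed(t_mid_clock)),
            "in_break": overlap > (t1 - t0) / 2.0,
            "amp_p10": float(p10),
            "amp_p50": float(p50),
            "amp_p90": float(p90),
        }
        freqs, psd = signal.welch(
            seg, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
        )
        try:
            row["mnf"] = mean_power_frequency(freqs, psd, band)
            row["mdf"] = median_power_frequency(freqs, psd, band)
            fmask = (freqs >= band[0]) & (freqs <= band[1])
            row["total_power"] = float(np.trapezoid(psd[fmask], freqs[fmask]))
            row["anomalous"] = False
        except SpectralError:
            row.update(mnf=np.nan, mdf=np.nan, total_power=0.0, anomalous=True)
        rows.append(row)
    if not rows:
        return _empty_features()
    return pd.DataFrame(rows)


def _empty_features() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "subject_id", "side", "window_index", "t_mid", "t_work", "in_break",
            "amp_p10", "amp_p50", "amp_p90", "mnf", "mdf", "total_power", "anomalous",
        ]
    )


def detect_anomalous_windows(
    features: pd.DataFrame,
    *,
    variance_fraction: float = 0.90,
    chi2_quantile: float = 0.999,
    min_windows: int = 10,
) -> pd.DataFrame:
    """Flag contaminated windows by robust distance in PCA space.

    Per subject-side, the screened feature matrix (amplitude percentiles,
    MNF, MDF, total power) is z-scored and projected onto the principal
    components covering ``variance_fraction`` of variance. In that space a
    robust squared distance (median center, MAD scale per component) is
    referred to a chi-square threshold at ``chi2_quantile``; windows beyond
    it are flagged. Groups with fewer than ``min_windows`` windows pass
    through unflagged with a warning, and constant feature columns are
    dropped from the screen.
    """
    out = features.copy()
    if "anomalous" not in out.columns:
        out["anomalous"] = False
    for (_, _), idx in out.groupby(["subject_id", "side"]).groups.items():
        sub = out.loc[idx]
        usable = sub.index[~sub[SCREEN_FEATURES].isna().any(axis=1)]
        if len(usable) < min_windows:
            warnings.warn(
                "fewer than %d windows for %s/%s: anomaly screen skipped"
                % (min_windows, sub.subject_id.iloc[0], sub.side.iloc[0])
            )
            continue
        X = sub.loc[usable, SCREEN_FEATURES].to_numpy(dtype=float)
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.any():
            continue  # all windows identical: nothing to flag
        if not keep.all():
            warnings.warn("constant feature column(s) dropped from anomaly screen")
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        pca = PCA()
        scores = pca.fit_transform(Z)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance_fraction) + 1)
        k = min(k, scores.shape[1])
        s = scores[:, :k]
        center = np.median(s, axis=0)
        mad = np.median(np.abs(s - center), axis=0) * 1.4826
        mad[mad == 0] = np.inf  # a constant score direction carries no evidence
        d2 = np.sum(((s - center) / mad) ** 2, axis=1)
        thresh = stats.chi2.ppf(chi2_quantile, df=k)
        out.loc[usable[d2 > thresh], "anomalous"] = True
    return out


@dataclass(frozen=True)
class FatigueSlope:
    """Per subject-side OLS fit of the fatigue metric on time."""

    subject_id: str
    side: str
    b0: float
    b_time: float
    stderr: float
    r_squared: float
    n_windows: int

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.b_time)


def fit_fatigue_slope(
    features: pd.DataFrame,
    *,
    metric: str = "mdf",
    time_col: str = "t_work",
    exclude_break: bool = True,
) -> FatigueSlope:
    """OLS slope of the fatigue metric over time for one subject-side.

    Break and anomalous windows are excluded; fewer than 3 usable windows
    yields a missing (NaN) record rather than an error. ``time_col`` selects
    the regressor convention: cumulative work minutes (default, matches a
    fatigue process that pauses during rest) or clock minutes (``"t_mid"``).
    """
    sid = features.subject_id.iloc[0] if len(features) else "?"
    side = features.side.iloc[0] if len(features) else "?"
    use = features[~features["anomalous"]]
    if exclude_break:
        use = use[~use["in_break"]]
    use = use.dropna(subset=[metric, time_col])
    if len(use) < 3 or use[time_col].nunique() < 2:
        return FatigueSlope(sid, side, np.nan, np.nan, np.nan, np.nan, len(use))
    res = stats.linregress(use[time_col].to_numpy(), use[metric].to_numpy())
    return FatigueSlope(
        subject_id=sid,
        side=side,
        b0=float(res.intercept),
        b_time=float(res.slope),
        stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_windows=len(use),
    )


def fatigue_slope_table(
    features: pd.DataFrame,
    *,
    metric: str = "mdf",
    time_col: str = "t_work",
    exclude_break: bool = True,
) -> pd.DataFrame:
    """Per-subject-side fatigue slopes as a tidy frame (missing fits kept)."""
    rows = []
    for (sid, side), sub in features.groupby(["subject_id", "side"]):
        fit = fit_fatigue_slope(
            sub, metric=metric, time_col=time_col, exclude_break=exclude_break
        )
        rows.append(
            {
                "subject_id": sid,
                "side": side,
                "b0": fit.b0,
                "b_time": fit.b_time,
                "stderr": fit.stderr,
                "r_squared": fit.r_squared,
                "n_windows": fit.n_windows,
                "missing": fit.missing,
            }
        )
    return pd.DataFrame(rows)


def pooled_slope_model(
    features: pd.DataFrame,
    *,
    metric: str = "mdf",
    time_col: str = "t_work",
    exclude_break: bool = True,
) -> dict:
    """Fixed-effects pooled fatigue model: metric ~ time + side + subject.

    Adjusting for muscle side and subject removes the between-recording level
    differences (the bimodality of raw MDF) so the time coefficient is the
    pooled within-recording fatigue rate. Returns the pooled coefficient with
    its standard error and p-value plus the per-subject-side residual slopes
    (slopes refit on the level-adjusted residuals) used downstream.
    """
    import statsmodels.formula.api as smf

    use = features[~features["anomalous"]]
    if exclude_break:
        use = use[~use["in_break"]]
    use = use.dropna(subset=[metric, time_col]).copy()
    if use.subject_id.nunique() < 2:
        raise ValueError("pooled model requires at least 2 subjects")
    formula = f"{metric} ~ {time_col} + C(side) + C(subject_id)"
    fit = smf.ols(formula, data=use).fit()
    coef = fit.params[time_col]
    # residual slopes: remove the fitted side+subject level shifts, refit per group
    level = fit.fittedvalues - fit.params.get("Intercept", 0.0) - coef * use[time_col]
    adj = use.assign(_adj=use[metric] - level)
    resid_rows = []
    for (sid, side), sub in adj.groupby(["subject_id", "side"]):
        if len(sub) >= 3 and sub[time_col].nunique() >= 2:
            r = stats.linregress(sub[time_col], sub["_adj"])
            resid_rows.append(
                {"subject_id": sid, "side": side, "residual_slope": float(r.slope)}
            )
    return {
        "b_time": float(coef),
        "stderr": float(fit.bse[time_col]),
        "p_value": float(fit.pvalues[time_col]),
        "n_windows": int(len(use)),
        "n_subjects": int(use.subject_id.nunique()),
        "r_squared": float(fit.rsquared),
        "residual_slopes": pd.DataFrame(resid_rows),
    }
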