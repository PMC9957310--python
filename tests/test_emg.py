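import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from ergofield.emg import (
    EmgRecording,
    SpectralError,
    bandpass,
    detect_anomalous_windows,
    fatigue_slope_table,
    fit_fatigue_slope,
    mean_power_frequency,
    median_power_frequency,
    pooled_slope_model,
    window_features,
)

FS = 1000.0


def _rec(samples, subject="S01", side="left", start=27000):
    return EmgRecording(
        subject_id=subject, side=side, sampling_rate=FS,
        start_time_s=start, samples=samples,
    )


def _sine(freq, duration_s, amp=1.0):
    t = np.arange(int(duration_s * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_stop_band_suppresses_5hz(self):
        out = bandpass(_rec(_sine(5, 10)))
        assert np.sqrt(np.mean(out.samples**2)) < 0.01 * np.sqrt(0.5)

    def test_pass_band_preserves_100hz(self):
        out = bandpass(_rec(_sine(100, 10)))
        in_rms = np.sqrt(0.5)
        assert np.sqrt(np.mean(out.samples**2)) == pytest.approx(in_rms, rel=0.05)

    def test_octave_beyond_low_cutoff_40db(self):
        out = bandpass(_rec(_sine(10, 10)))  # one octave below 20 Hz
        atten = 20 * np.log10(np.sqrt(np.mean(out.samples**2)) / np.sqrt(0.5))
        assert atten < -40

    def test_white_noise_psd_flat_in_passband(self, rng):
        """Periodogram oracle: in-band PSD of filtered white noise is flat."""
        x = rng.standard_normal(int(60 * FS))
        out = bandpass(_rec(x))
        f, p = signal.welch(out.samples, fs=FS, nperseg=1024)
        mid = (f > 60) & (f < 350)  # clear of both transition bands
        assert p[mid].std() / p[mid].mean() < 0.15
        stop = f < 8
        assert p[stop].mean() < 1e-3 * p[mid].mean()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_rec(np.zeros(1000)), low=450, high=20)


class TestMedianPowerFrequency:
    def test_point_mass(self):
        f = np.arange(20, 451, 1.0)
        p = np.zeros_like(f)
        p[f == 150] = 3.0
        assert median_power_frequency(f, p) == pytest.approx(150.0, abs=1.0)

    def test_two_equal_bins_interpolates_midway(self):
        # equal densities at 100 and 200 Hz only: trapezoid cumulative is
        # linear between them, so the half-power point is 150 Hz
        f = np.array([100.0, 200.0])
        p = np.array([1.0, 1.0])
        assert median_power_frequency(f, p) == pytest.approx(150.0)

    def test_uniform_band_gives_midpoint(self):
        f = np.linspace(20, 450, 1000)
        p = np.ones_like(f)
        assert median_power_frequency(f, p) == pytest.approx(235.0, abs=0.5)
        assert mean_power_frequency(f, p) == pytest.approx(235.0, abs=0.5)

    def test_zero_power_undefined(self):
        f = np.linspace(20, 450, 100)
        with pytest.raises(SpectralError):
            median_power_frequency(f, np.zeros_like(f))
        with pytest.raises(SpectralError):
            mean_power_frequency(f, np.zeros_like(f))

    def test_negative_density_rejected(self):
        with pytest.raises(SpectralError):
            median_power_frequency(np.array([100.0, 200.0]), np.array([1.0, -1.0]))


class TestWindowFeatures:
    def test_pure_sine_mdf_within_one_bin(self, smoke_schedule):
        rec = _rec(_sine(100, 600), start=smoke_schedule.shift_start)
        feats = window_features(rec, smoke_schedule)
        assert len(feats) == 1
        assert feats.mdf.iloc[0] == pytest.approx(100.0, abs=1.0)
        assert feats.mnf.iloc[0] == pytest.approx(100.0, abs=1.0)

    def test_bandlimited_white_noise_mdf_at_band_center(self, rng, smoke_schedule):
        x = rng.standard_normal(int(600 * FS))
        rec = bandpass(_rec(x, start=smoke_schedule.shift_start))
        feats = window_features(rec, smoke_schedule)
        # flat PSD on [20, 450] puts the median at the band midpoint; the
        # Butterworth transition bands pull it slightly inward
        assert feats.mdf.iloc[0] == pytest.approx(235.0, abs=5.0)

    def test_zero_window_flagged_anomalous(self, smoke_schedule):
        rec = _rec(np.zeros(int(600 * FS)), start=smoke_schedule.shift_start)
        feats = window_features(rec, smoke_schedule)
        assert bool(feats.anomalous.iloc[0])
        assert feats.total_power.iloc[0] == 0.0

    def test_short_recording_warns_and_returns_empty(self, smoke_schedule):
        rec = _rec(np.zeros(1000), start=smoke_schedule.shift_start)
        with pytest.warns(UserWarning):
            feats = window_features(rec, smoke_schedule)
        assert feats.empty

    def test_amplitude_percentiles_ordered_and_break_flagged(
        self, smoke_emg_features
    ):
        f = smoke_emg_features
        assert (f.amp_p10 <= f.amp_p50).all() and (f.amp_p50 <= f.amp_p90).all()
        assert f.in_break.sum() == 1  # the 10-min break window of the smoke shift
        assert ((f.mdf >= 20) & (f.mdf <= 450)).all()

    def test_frequency_scaling_property(self, smoke_schedule, rng):
        """Time-compressing a band-confined signal by k scales MDF by k."""
        x = rng.standard_normal(int(600 * FS))
        sos = signal.butter(4, [60, 140], btype="bandpass", fs=FS, output="sos")
        x = signal.sosfiltfilt(sos, x)
        k = 1.25  # keep 1.25*140 Hz well inside the analysis band
        compressed = signal.resample_poly(x, up=4, down=5)  # same fs, k x freq
        f1 = window_features(_rec(x, start=smoke_schedule.shift_start), smoke_schedule)
        f2 = window_features(
            _rec(np.tile(compressed, 2)[: x.size], start=smoke_schedule.shift_start),
            smoke_schedule,
        )
        assert f2.mdf.iloc[0] / f1.mdf.iloc[0] == pytest.approx(k, rel=0.02)

    def test_mdf_invariant_to_amplitude_scaling(self, smoke_schedule, rng):
        x = signal.sosfiltfilt(
            signal.butter(4, [40, 160], btype="bandpass", fs=FS, output="sos"),
            rng.standard_normal(int(600 * FS)),
        )
        f1 = window_features(_rec(x, start=smoke_schedule.shift_start), smoke_schedule)
        f2 = window_features(
            _rec(7.5 * x, start=smoke_schedule.shift_start), smoke_schedule
        )
        assert f2.mdf.iloc[0] == pytest.approx(f1.mdf.iloc[0], abs=1e-9)
        assert f2.amp_p50.iloc[0] == pytest.approx(7.5 * f1.amp_p50.iloc[0])


def _feature_frame(rng, n=40, subject="S01", side="left"):
    """Synthetic well-behaved feature rows (no signal processing involved)."""
    base = {
        "amp_p10": 0.02, "amp_p50": 0.10, "amp_p90": 0.25,
        "mnf": 90.0, "mdf": 88.0, "total_power": 0.02,
    }
    rows = []
    for i in range(n):
        row = {
            "subject_id": subject, "side": side, "window_index": i,
            "t_mid": 5 + 10.0 * i, "t_work": 5 + 10.0 * i, "in_break": False,
            "anomalous": False,
        }
        for k, v in base.items():
            row[k] = v * (1 + 0.03 * rng.standard_normal())
        rows.append(row)
    return pd.DataFrame(rows)


class TestAnomalyScreen:
    def test_clean_windows_rarely_flagged(self, rng):
        f = _feature_frame(rng, n=200)
        out = detect_anomalous_windows(f)
        assert out.anomalous.mean() <= 0.01

    def test_gross_outlier_windows_flagged(self, rng):
        f = _feature_frame(rng, n=40)
        bad = [5, 17, 30]
        f.loc[bad, ["mdf", "mnf"]] = [[30.0, 35.0]] * len(bad)
        f.loc[bad, "total_power"] *= 40
        out = detect_anomalous_windows(f)
        assert out.loc[bad, "anomalous"].all()
        assert not out.drop(index=bad).anomalous.any()

    def test_identical_windows_none_flagged(self):
        f = _feature_frame(np.random.default_rng(0), n=15)
        for c in ["amp_p10", "amp_p50", "amp_p90", "mnf", "mdf", "total_power"]:
            f[c] = f[c].iloc[0]
        out = detect_anomalous_windows(f)
        assert not out.anomalous.any()

    def test_too_few_windows_pass_through(self, rng):
        f = _feature_frame(rng, n=5)
        with pytest.warns(UserWarning):
            out = detect_anomalous_windows(f)
        assert not out.anomalous.any()


class TestFatigueSlope:
    def test_exact_line_recovered(self, rng):
        f = _feature_frame(rng, n=20)
        f["mdf"] = 80.0 - 0.05 * f["t_work"]
        fit = fit_fatigue_slope(f)
        assert fit.b_time == pytest.approx(-0.05, abs=1e-12)
        assert fit.b0 == pytest.approx(80.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_metric_zero_slope(self, rng):
        f = _feature_frame(rng, n=10)
        f["mdf"] = 77.0
        assert fit_fatigue_slope(f).b_time == pytest.approx(0.0, abs=1e-12)

    def test_break_and_anomalous_windows_excluded(self, rng):
        f = _feature_frame(rng, n=12)
        f["mdf"] = 80.0 - 0.05 * f["t_work"]
        f.loc[3, "in_break"] = True
        f.loc[7, "anomalous"] = True
        f.loc[[3, 7], "mdf"] = 300.0  # would wreck the fit if included
        fit = fit_fatigue_slope(f)
        assert fit.n_windows == 10
        assert fit.b_time == pytest.approx(-0.05, abs=1e-12)

    def test_insufficient_windows_missing_record(self, rng):
        f = _feature_frame(rng, n=2)
        fit = fit_fatigue_slope(f)
        assert fit.missing and np.isnan(fit.b_time)

    def test_table_covers_all_subject_sides(self, rng):
        f = pd.concat(
            [
                _feature_frame(rng, n=8, subject="S01", side="left"),
                _feature_frame(rng, n=8, subject="S01", side="right"),
                _feature_frame(rng, n=8, subject="S02", side="left"),
            ],
            ignore_index=True,
        )
        tab = fatigue_slope_table(f)
        assert len(tab) == 3 and not tab.missing.any()


class TestPooledSlopeModel:
    def _two_subject_frame(self, rng, slope=-0.04, side_offset=0.0):
        frames = []
        for sid, icpt in (("S01", 85.0), ("S02", 70.0)):
            for side in ("left", "right"):
                f = _feature_frame(rng, n=10, subject=sid, side=side)
                off = side_offset if side == "right" else 0.0
                f["mdf"] = icpt + off + slope * f["t_work"]
                frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def test_shared_slope_recovered_across_intercepts(self, rng):
        f = self._two_subject_frame(rng, slope=-0.04)
        out = pooled_slope_model(f)
        assert out["b_time"] == pytest.approx(-0.04, abs=1e-10)

    def test_side_offset_does_not_bias_time_coefficient(self, rng):
        f0 = self._two_subject_frame(rng, slope=-0.04, side_offset=0.0)
        f5 = f0.copy()
        f5.loc[f5.side == "right", "mdf"] += 5.0
        out0, out5 = pooled_slope_model(f0), pooled_slope_model(f5)
        assert out5["b_time"] == pytest.approx(out0["b_time"], abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        """Brute-force least squares on the dummy-coded design matrix."""
        f = self._two_subject_frame(rng)
        f["mdf"] += 0.5 * rng.standard_normal(len(f))  # heterogeneous noise
        out = pooled_slope_model(f)
        X = np.column_stack(
            [
                np.ones(len(f)),
                f.t_work,
                (f.side == "right").astype(float),
                (f.subject_id == "S02").astype(float),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ f.mdf.to_numpy())
        assert out["b_time"] == pytest.approx(beta[1], abs=1e-8)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            pooled_slope_model(_feature_frame(rng, n=10))
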