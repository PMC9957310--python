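"""End-to-end pipeline: simulate -> clean -> derive -> associate -> report.

Stages exchange tidy CSVs on disk so each can also be fed real exported
sensor data in the same dialects. Every run writes a manifest with the
config snapshot, per-stage record counts (kept + rejected reconcile to the
input) and SHA-256 checksums of all outputs, so a rerun with the same seed
and config is verifiably byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import association_battery
from .emg import (
    EmgRecording,
    bandpass,
    detect_anomalous_windows,
    fatigue_slope_table,
    pooled_slope_model,
    window_features,
)
from .heartrate import HeartRateSeries, hrr_table, sqrt_transform_with_normality
from .schedule import ShiftSchedule
from .surveys import cr10_shift_change, delta_from_baseline, validate_responses
from .synthetic import (
    CohortSpec,
    GroundTruth,
    default_ground_truth,
    simulate_cohort,
    simulate_emg,
    simulate_heart_rate,
    simulate_surveys,
)

log = logging.getLogger("ergofield")


@dataclass
class RunConfig:
    """Every tunable of a pipeline run; round-trips losslessly through YAML."""

    # cohort
    n_per_group: int = 8
    groups: tuple[str, ...] = ("Ground", "Ladder", "Platform")
    age_range: tuple[int, int] = (18, 47)
    seed: int = 0
    # schedule: a named preset or explicit clock times via `schedule`
    schedule_preset: str = "standard"
    break_minutes: int = 30
    schedule: dict | None = None
    # ground-truth overrides passed to the generator (see default_ground_truth)
    truth: dict = field(default_factory=dict)
    # heart rate
    hr_median_window: int = 5
    hr_min_coverage: float = 0.5
    # EMG
    emg_band: tuple[float, float] = (20.0, 450.0)
    emg_filter_order: int = 4
    emg_window_s: int = 600
    anomaly_chi2_quantile: float = 0.999
    anomaly_variance_fraction: float = 0.90
    mpf_definition: str = "median"  # or "mean"
    time_basis: str = "work"  # or "clock"
    # association
    outcome_scale: str = "hrr_sqrt"  # or "hrr"

    def __post_init__(self) -> None:
        if self.mpf_definition not in ("median", "mean"):
            raise ValueError("mpf_definition must be 'median' or 'mean'")
        if self.time_basis not in ("work", "clock"):
            raise ValueError("time_basis must be 'work' or 'clock'")
        if self.outcome_scale not in ("hrr_sqrt", "hrr"):
            raise ValueError("outcome_scale must be 'hrr_sqrt' or 'hrr'")
        if not 0 < self.anomaly_chi2_quantile < 1:
            raise ValueError("anomaly_chi2_quantile must be in (0, 1)")

    @property
    def metric_col(self) -> str:
        return "mdf" if self.mpf_definition == "median" else "mnf"

    @property
    def time_col(self) -> str:
        return "t_work" if self.time_basis == "work" else "t_mid"

    def build_schedule(self) -> ShiftSchedule:
        if self.schedule is not None:
            return ShiftSchedule.from_dict(self.schedule)
        if self.schedule_preset == "standard":
            return ShiftSchedule.standard(break_minutes=self.break_minutes)
        if self.schedule_preset == "smoke":
            return ShiftSchedule.smoke()
        raise ValueError(f"unknown schedule preset {self.schedule_preset!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = list(self.groups)
        d["age_range"] = list(self.age_range)
        d["emg_band"] = list(self.emg_band)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("groups", "age_range", "emg_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# CSV dialects


def write_heart_rate_csv(path: Path, series: dict[str, HeartRateSeries]) -> None:
    frames = [
        pd.DataFrame(
            {"subject_id": s.subject_id, "time_s": s.time_s, "bpm": np.round(s.bpm, 3)}
        )
        for s in series.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_heart_rate_csv(path: Path) -> dict[str, HeartRateSeries]:
    df = pd.read_csv(path)
    out = {}
    for sid, sub in df.groupby("subject_id", sort=False):
        out[str(sid)] = HeartRateSeries(
            subject_id=str(sid),
            time_s=sub.time_s.to_numpy(),
            bpm=sub.bpm.to_numpy(),
        )
    return out


def write_emg_csv(path: Path, rec: EmgRecording) -> None:
    """Single-channel EMG dialect: one metadata comment line + amplitude column."""
    header = (
        f"# subject_id={rec.subject_id} side={rec.side} "
        f"start_time={rec.start_time_s} sampling_rate={rec.sampling_rate:g}\n"
        "amplitude_mv\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame({"a": np.round(rec.samples, 5)}).to_csv(
            fh, index=False, header=False
        )


def read_emg_csv(path: Path) -> EmgRecording:
    with open(path) as fh:
        meta_line = fh.readline()
    if not meta_line.startswith("#"):
        raise ValueError(f"{path}: missing EMG metadata header line")
    meta = dict(tok.split("=", 1) for tok in meta_line[1:].split())
    samples = pd.read_csv(path, skiprows=1)["amplitude_mv"].to_numpy(dtype=float)
    return EmgRecording(
        subject_id=meta["subject_id"],
        side=meta["side"],
        sampling_rate=float(meta["sampling_rate"]),
        start_time_s=int(meta["start_time"]),
        samples=np.atleast_1d(samples),
    )


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "exertion": truth.exertion.to_dict(orient="records"),
        "hr_sit": truth.hr_sit,
        "emg_params": truth.emg_params.to_dict(orient="records"),
        "hr_gain": truth.hr_gain,
        "hr_noise_bpm": truth.hr_noise_bpm,
        "hr_spike_rate": truth.hr_spike_rate,
        "emg_mdf_intercept": truth.emg_mdf_intercept,
        "emg_mdf_slope": truth.emg_mdf_slope,
        "emg_bandwidth_hz": truth.emg_bandwidth_hz,
        "emg_amplitude_mv": truth.emg_amplitude_mv,
        "rating_rank_correlation": truth.rating_rank_correlation,
    }


def _truth_from_json(d: dict) -> GroundTruth:
    return GroundTruth(
        exertion=pd.DataFrame(d["exertion"]),
        hr_sit=d["hr_sit"],
        emg_params=pd.DataFrame(d["emg_params"]),
        hr_gain=d["hr_gain"],
        hr_noise_bpm=d["hr_noise_bpm"],
        hr_spike_rate=d["hr_spike_rate"],
        emg_mdf_intercept=d["emg_mdf_intercept"],
        emg_mdf_slope=d["emg_mdf_slope"],
        emg_bandwidth_hz=d["emg_bandwidth_hz"],
        emg_amplitude_mv=d["emg_amplitude_mv"],
        rating_rank_correlation=d["rating_rank_correlation"],
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stages


def run_simulate(config: RunConfig, outdir: str | Path) -> Path:
    """Generate a dataset directory: roster, HR, EMG, surveys + truth JSON."""
    outdir = Path(outdir)
    (outdir / "emg").mkdir(parents=True, exist_ok=True)
    schedule = config.build_schedule()
    spec = CohortSpec(
        n_per_group=config.n_per_group,
        groups=config.groups,
        age_range=config.age_range,
        seed=config.seed,
    )
    roster = simulate_cohort(spec)
    truth = default_ground_truth(roster, seed=config.seed, **config.truth)
    roster.to_csv(outdir / "roster.csv", index=False)
    hr = {
        sid: simulate_heart_rate(sid, schedule, truth, seed=config.seed)
        for sid in roster.subject_id
    }
    write_heart_rate_csv(outdir / "heart_rate.csv", hr)
    for sid in roster.subject_id:
        for side in ("left", "right"):
            rec = simulate_emg(sid, side, schedule, truth, seed=config.seed)
            write_emg_csv(outdir / "emg" / f"{sid}_{side}.csv", rec)
    simulate_surveys(roster, truth, seed=config.seed).to_csv(
        outdir / "surveys.csv", index=False
    )
    (outdir / "ground_truth.json").write_text(
        json.dumps(_truth_to_json(truth), indent=1, sort_keys=True)
    )
    (outdir / "schedule.yaml").write_text(yaml.safe_dump(schedule.to_dict()))
    config.to_yaml(outdir / "config.yaml")
    log.info("simulated %d subjects into %s", len(roster), outdir)
    return outdir


def run_analysis(config: RunConfig, dataset: str | Path, outdir: str | Path) -> dict:
    """Run the full derivation + association battery on a dataset directory.

    Writes all result tables plus ``manifest.json`` and returns the in-memory
    results dict. Subjects with missing signals yield missing-value records,
    not silent drops; the manifest reconciles counts per stage.
    """
    dataset, outdir = Path(dataset), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schedule = ShiftSchedule.from_dict(
        yaml.safe_load((dataset / "schedule.yaml").read_text())
    )
    roster = pd.read_csv(dataset / "roster.csv")
    counts: dict[str, dict] = {}

    # --- heart rate -> %HRR
    hr = read_heart_rate_csv(dataset / "heart_rate.csv")
    hrr = hrr_table(
        hr, roster, schedule,
        median_window=config.hr_median_window,
        min_coverage=config.hr_min_coverage,
    )
    norm = sqrt_transform_with_normality(hrr.hrr.to_numpy())
    counts["heart_rate"] = {
        "subjects_with_series": len(hr),
        "hrr_rows": int(len(hrr)),
        "hrr_missing": int(hrr.missing.sum()),
        "hrr_negative_excluded_from_sqrt": norm.n_excluded_negative,
    }
    hrr.to_csv(outdir / "hrr.csv", index=False)

    # --- EMG -> window features -> slopes
    feats = []
    emg_files = sorted((dataset / "emg").glob("*.csv"))
    for path in emg_files:
        rec = read_emg_csv(path)
        rec = bandpass(
            rec, config.emg_band[0], config.emg_band[1], config.emg_filter_order
        )
        feats.append(
            window_features(rec, schedule, window_length_s=config.emg_window_s)
        )
    features = (
        pd.concat(feats, ignore_index=True) if feats else pd.DataFrame()
    )
    if len(features):
        features = detect_anomalous_windows(
            features,
            variance_fraction=config.anomaly_variance_fraction,
            chi2_quantile=config.anomaly_chi2_quantile,
        )
    features.to_csv(outdir / "emg_features.csv", index=False)
    slopes = fatigue_slope_table(
        features, metric=config.metric_col, time_col=config.time_col
    ) if len(features) else pd.DataFrame(
        columns=["subject_id", "side", "b0", "b_time", "stderr", "r_squared",
                 "n_windows", "missing"]
    )
    # recordings absent from the dataset still get a missing record
    have = set(zip(slopes.subject_id, slopes.side)) if len(slopes) else set()
    missing_rows = [
        {"subject_id": sid, "side": side, "b0": np.nan, "b_time": np.nan,
         "stderr": np.nan, "r_squared": np.nan, "n_windows": 0, "missing": True}
        for sid in roster.subject_id for side in ("left", "right")
        if (sid, side) not in have
    ]
    if missing_rows:
        slopes = pd.concat([slopes, pd.DataFrame(missing_rows)], ignore_index=True)
        slopes = slopes.sort_values(["subject_id", "side"]).reset_index(drop=True)
    slopes.to_csv(outdir / "fatigue_slopes.csv", index=False)
    counts["emg"] = {
        "recordings": len(emg_files),
        "windows": int(len(features)),
        "windows_rejected": int(features.anomalous.sum()) if len(features) else 0,
        "slopes_reported": int((~slopes.missing).sum()) if len(slopes) else 0,
        "slopes_missing": int(slopes.missing.sum()) if len(slopes) else 0,
    }
    pooled = None
    usable = features[~features.anomalous] if len(features) else features
    if len(usable) and usable.subject_id.nunique() >= 2:
        pooled = pooled_slope_model(
            features, metric=config.metric_col, time_col=config.time_col
        )
        (outdir / "pooled_slope.json").write_text(
            json.dumps(
                {k: v for k, v in pooled.items() if k != "residual_slopes"},
                indent=1, sort_keys=True,
            )
        )

    # --- surveys
    raw_surveys = pd.read_csv(dataset / "surveys.csv")
    responses, rejected = validate_responses(raw_surveys)
    deltas, delta_missing = delta_from_baseline(responses)
    cr10 = cr10_shift_change(responses, roster)
    counts["surveys"] = {
        "rows_in": int(len(raw_surveys)),
        "rows_accepted": int(len(responses)),
        "rows_rejected": int(len(rejected)),
        "deltas": int(len(deltas)),
        "baselines_missing": int(len(delta_missing)),
    }
    responses.to_csv(outdir / "survey_responses.csv", index=False)
    rejected.to_csv(outdir / "survey_rejections.csv", index=False)
    deltas.to_csv(outdir / "survey_deltas.csv", index=False)
    cr10.to_csv(outdir / "cr10_changes.csv", index=False)

    # --- association battery
    battery = association_battery(
        hrr, deltas, slopes, cr10, roster, outcome_scale=config.outcome_scale
    )
    battery["associations"].to_csv(outdir / "associations.csv", index=False)
    effects_json = [
        {
            "outcome": e.outcome,
            "factor": e.factor,
            "method": e.method,
            "omnibus_stat": e.omnibus_stat,
            "omnibus_p": e.omnibus_p,
            "pairwise": e.pairwise.to_dict(orient="records"),
        }
        for e in battery["group_effects"]
    ]
    (outdir / "group_effects.json").write_text(
        json.dumps(effects_json, indent=1, sort_keys=True, default=float)
    )

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_counts": counts,
        "normality": {
            "shapiro_before": norm.shapiro_before,
            "shapiro_after": norm.shapiro_after,
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    log.info("analysis complete: %s", outdir)
    return {
        "hrr": hrr,
        "features": features,
        "slopes": slopes,
        "pooled": pooled,
        "deltas": deltas,
        "cr10": cr10,
        "battery": battery,
        "manifest": manifest,
    }


#: recovery tolerances: generator noise propagated through each estimator.
#: The rank-correlation band is sample-size dependent (2 x the Fisher
#: standard error 1/sqrt(n-3) at the realized number of rating pairs).
RECOVERY_TOLERANCES = {
    "hr_work_bpm": 2.0,  # 2*SEM bound at sigma=3 bpm over a >=600-sample window
    "hrr": 0.05,
    "b_time_hz_per_min": 0.02,  # window-MDF noise over a short window grid
    "rank_correlation": "2_fisher_se",
}


def run_recovery_report(
    config: RunConfig, dataset: str | Path, results: str | Path
) -> dict:
    """Compare pipeline estimates with the generator's ground truth.

    Refuses to run without ``ground_truth.json`` (real-data mode has no
    truth). Emits per-quantity mean absolute errors and pass/fail against
    the documented tolerances.
    """
    dataset, results = Path(dataset), Path(results)
    truth_path = dataset / "ground_truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(
            "no ground_truth.json: recovery reporting requires simulated data"
        )
    truth = _truth_from_json(json.loads(truth_path.read_text()))
    hrr = pd.read_csv(results / "hrr.csv")
    slopes = pd.read_csv(results / "fatigue_slopes.csv")
    responses = pd.read_csv(results / "survey_responses.csv")

    report: dict = {"quantities": {}, "tolerances": RECOVERY_TOLERANCES}

    # heart-rate work means and %HRR against closed-form generator targets
    hr_err, hrr_err = [], []
    for _, row in hrr[~hrr.missing].iterrows():
        ex = truth.exertion_of(row.subject_id, row.period)
        target_work = truth.hr_sit[row.subject_id] + truth.hr_gain * ex
        hr_err.append(abs(row.hr_work - target_work))
        rest = truth.hr_sit[row.subject_id] - 10.0
        target_hrr = (target_work - rest) / (row.hr_max - rest)
        hrr_err.append(abs(row.hrr - target_hrr))
    report["quantities"]["hr_work_bpm"] = {
        "mean_abs_error": float(np.mean(hr_err)) if hr_err else None,
        "n": len(hr_err),
    }
    report["quantities"]["hrr"] = {
        "mean_abs_error": float(np.mean(hrr_err)) if hrr_err else None,
        "n": len(hrr_err),
    }

    ok = slopes[~slopes.missing].merge(
        truth.emg_params, on=["subject_id", "side"]
    )
    report["quantities"]["b_time_hz_per_min"] = {
        "mean_abs_error": float((ok.b_time - ok.slope_hz_per_min).abs().mean())
        if len(ok) else None,
        "n": int(len(ok)),
    }

    # realized rating-exertion rank correlation vs programmed value
    from .association import spearman_correlation

    merged = responses[responses.scale == "BorgRPE"].merge(
        truth.exertion.rename(columns={"period": "timepoint"}),
        on=["subject_id", "timepoint"],
    )
    if len(merged) >= 3:
        rho, _, _ = spearman_correlation(merged.value, merged.exertion)
        report["quantities"]["rank_correlation"] = {
            "mean_abs_error": abs(rho - truth.rating_rank_correlation),
            "estimate": rho,
            "target": truth.rating_rank_correlation,
            "n": int(len(merged)),
        }

    passed = {}
    for name, tol in RECOVERY_TOLERANCES.items():
        q = report["quantities"].get(name)
        err = q.get("mean_abs_error") if q else None
        if tol == "2_fisher_se":
            n = q.get("n", 0) if q else 0
            tol = 2.0 / np.sqrt(max(n - 3, 1))
            report["tolerances"] = dict(report["tolerances"], **{name: tol})
        passed[name] = bool(err is not None and err <= tol)
    report["passed"] = passed
    report["all_passed"] = all(passed.values())
    (results / "recovery.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report
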