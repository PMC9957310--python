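"""Monte-Carlo validation batteries: parameter recovery and test calibration.

These routines run the *actual* pipeline estimators on freshly generated
synthetic data and summarize how well the known ground truth is recovered:
the MDF fatigue-slope sweep, the PCA anomaly-screen operating point, the
type-I error of the association tests under the generator's null, and the
behaviour of the rating correlations across programmed effect sizes. They
back both the acceptance checks and the `recover`-style reporting, and are
deliberately sized for a single CPU (shortened shifts, modest replicate
counts; see the methods note).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    adjusted_regression,
    kruskal_wallis,
    pearson_correlation,
    spearman_correlation,
)
from .emg import bandpass, detect_anomalous_windows, fit_fatigue_slope, window_features
from .heartrate import hrr_table
from .schedule import ShiftSchedule
from .surveys import cr10_shift_change, delta_from_baseline
from .synthetic import (
    CohortSpec,
    default_ground_truth,
    expected_mdf,
    simulate_cohort,
    simulate_emg,
    simulate_heart_rate,
    simulate_surveys,
)


def recovery_schedule() -> ShiftSchedule:
    """100-min shift, 10-min break: 9 work windows for slope Monte-Carlos."""
    return ShiftSchedule.from_times("7:30", "9:10", "8:50", break_minutes=10)


def short_schedule() -> ShiftSchedule:
    """60-min shift used where per-recording cost must stay minimal."""
    return ShiftSchedule.from_times("7:30", "8:30", "8:00", break_minutes=10)


def _single_subject_truth(seed: int, slope: float, intercept: float = 80.0):
    roster = simulate_cohort(CohortSpec(n_per_group=1, groups=("Ground",), seed=seed))
    truth = default_ground_truth(
        roster, seed=seed, emg_mdf_intercept=intercept, emg_mdf_slope=slope,
        emg_slope_sd=0.0, emg_intercept_sd=0.0, emg_side_offset_hz=0.0,
    )
    return roster, truth


def noiseless_slope(
    slope: float,
    schedule: ShiftSchedule | None = None,
    intercept: float = 80.0,
    bandwidth: float = 80.0,
) -> float:
    """Zero-noise limit: slope of the analytic window-MDF over the window grid.

    The windowed MDF of the noiseless generator is ``expected_mdf`` of the
    programmed center; fitting the same OLS the pipeline uses on those exact
    values gives the slope the estimator converges to as noise vanishes.
    """
    schedule = schedule or recovery_schedule()
    n_windows = int((schedule.shift_end - schedule.shift_start) // 600)
    t_mid = schedule.shift_start + 300 + 600 * np.arange(n_windows)
    in_break = np.asarray(schedule.in_break(t_mid))
    t_work = np.asarray(schedule.work_minutes_elapsed(t_mid.astype(float)))
    keep = ~in_break
    mdf = np.array(
        [expected_mdf(intercept + slope * t, bandwidth) for t in t_work[keep]]
    )
    return float(stats.linregress(t_work[keep], mdf).slope)


def slope_recovery(
    true_slopes=(-0.0, -0.005, -0.01, -0.05),
    n_reps: int = 100,
    seed: int = 0,
    schedule: ShiftSchedule | None = None,
) -> pd.DataFrame:
    """Recover the programmed MDF slope through the full estimation chain.

    Per replicate: synthesize one recording at default noise, bandpass,
    window, fit the per-recording OLS slope. Reports the mean recovered
    slope, its Monte-Carlo standard error, and the noiseless-limit target.
    """
    schedule = schedule or recovery_schedule()
    rows = []
    for slope in true_slopes:
        estimates = []
        for rep in range(n_reps):
            rep_seed = (seed * 100003 + rep * 997 + int(abs(slope) * 1e5)) % (2**31)
            _, truth = _single_subject_truth(rep_seed, slope)
            rec = simulate_emg("S01", "left", schedule, truth, seed=rep_seed)
            feats = window_features(bandpass(rec), schedule)
            fit = fit_fatigue_slope(feats)
            estimates.append(fit.b_time)
        estimates = np.asarray(estimates)
        rows.append(
            {
                "true_slope": float(slope),
                "mean_recovered": float(estimates.mean()),
                "mc_se": float(estimates.std(ddof=1) / np.sqrt(n_reps)),
                "mean_abs_error": float(np.abs(estimates - slope).mean()),
                "noiseless_limit": noiseless_slope(slope, schedule),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def anomaly_screen_rates(
    n_clean: int = 6,
    n_contaminated: int = 5,
    n_bad_windows: int = 5,
    seed: int = 0,
    schedule: ShiftSchedule | None = None,
) -> dict:
    """Operating point of the PCA screen on clean vs contaminated recordings.

    Clean recordings estimate the false-positive rate; contaminated ones
    (alternating clipping / 15-Hz drift windows) estimate sensitivity.
    """
    schedule = schedule or ShiftSchedule.from_times("7:30", "11:30", "9:20", 20)
    n_windows = int((schedule.shift_end - schedule.shift_start) // 600)
    clean_flagged = clean_total = 0
    hit = injected = 0
    for k in range(n_clean + n_contaminated):
        rep_seed = (seed * 7919 + k) % (2**31)
        _, truth = _single_subject_truth(rep_seed, -0.05)
        contaminated = k >= n_clean
        plan = None
        bad: list[int] = []
        if contaminated:
            rng = np.random.default_rng(rep_seed)
            bad = sorted(
                rng.choice(n_windows, size=n_bad_windows, replace=False).tolist()
            )
            plan = {
                w: ("clipping" if i % 2 == 0 else "drift")
                for i, w in enumerate(bad)
            }
        rec = simulate_emg(
            "S01", "left", schedule, truth, seed=rep_seed, artifact_windows=plan
        )
        feats = window_features(bandpass(rec), schedule)
        feats = detect_anomalous_windows(feats)
        if contaminated:
            injected += len(bad)
            hit += int(feats.set_index("window_index").loc[bad, "anomalous"].sum())
        else:
            clean_total += len(feats)
            clean_flagged += int(feats.anomalous.sum())
    return {
        "detection_rate": hit / injected if injected else float("nan"),
        "false_positive_rate": clean_flagged / clean_total if clean_total else 0.0,
        "n_injected": injected,
        "n_clean_windows": clean_total,
    }


def _null_cohort_tables(rep_seed: int, schedule: ShiftSchedule):
    roster = simulate_cohort(CohortSpec(n_per_group=8, seed=rep_seed))
    truth = default_ground_truth(roster, seed=rep_seed, rating_rank_correlation=0.0)
    hr = {
        sid: simulate_heart_rate(sid, schedule, truth, seed=rep_seed)
        for sid in roster.subject_id
    }
    hrr = hrr_table(hr, roster, schedule)
    surveys = simulate_surveys(roster, truth, seed=rep_seed)
    deltas, _ = delta_from_baseline(surveys)
    return roster, hrr, deltas


def type_one_error_calibration(
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    schedule: ShiftSchedule | None = None,
) -> pd.DataFrame:
    """Empirical size of the association tests under the generator's null.

    Ratings are decoupled from exertion (rank correlation 0), so every test
    of a rating-vs-direct-measure association should reject at its nominal
    level. One replicate is a fresh 24-worker cohort run through the real
    %HRR pipeline and survey delta coding; each test is evaluated on the
    end-of-shift period (one row per subject), the sampling unit over which
    the generator's null makes observations independent — pooling periods
    would correlate rows through the shared T0 baseline and miscalibrate
    every test by construction, not by implementation error.
    """
    from .association import overall_effort_table

    schedule = schedule or ShiftSchedule.smoke()
    rej = {"pearson": 0, "spearman": 0, "kruskal_wallis": 0, "adjusted_regression": 0}
    for rep in range(n_reps):
        rep_seed = (seed * 65537 + rep) % (2**31)
        roster, hrr, deltas = _null_cohort_tables(rep_seed, schedule)
        overall = overall_effort_table(hrr, deltas)
        sub = overall[overall.period == "T3"]
        _, p, _ = pearson_correlation(sub.hrr_sqrt, sub.BorgRPE_delta)
        rej["pearson"] += p < alpha
        _, p, _ = spearman_correlation(sub.hrr_sqrt, sub.BorgRPE_delta)
        rej["spearman"] += p < alpha
        borg = deltas[(deltas.scale == "BorgRPE") & (deltas.timepoint == "T3")].merge(
            roster[["subject_id", "group"]], on="subject_id"
        )
        _, p = kruskal_wallis(borg.delta, borg.group)
        rej["kruskal_wallis"] += p < alpha
        res = adjusted_regression(sub, "hrr_sqrt", "BorgRPE_delta", ("group",))
        rej["adjusted_regression"] += res.p_value < alpha
    se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return pd.DataFrame(
        [
            {"test": name, "empirical_alpha": count / n_reps,
             "nominal_alpha": alpha, "mc_se": se, "n_reps": n_reps}
            for name, count in rej.items()
        ]
    )


def rating_correlation_sweep(
    rho_grid=(0.0, 0.3, 0.6, 0.9),
    n_reps: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled Spearman between the Borg and Omni RPE deltas vs programmed rho.

    Both scales load on the same latent exertion, so their mutual rank
    correlation must increase monotonically with the programmed
    rating-exertion correlation and vanish at zero.
    """
    rows = []
    for rho in rho_grid:
        vals = []
        for rep in range(n_reps):
            rep_seed = (seed * 31337 + rep * 13 + int(rho * 1000)) % (2**31)
            roster = simulate_cohort(CohortSpec(n_per_group=8, seed=rep_seed))
            truth = default_ground_truth(
                roster, seed=rep_seed, rating_rank_correlation=rho
            )
            surveys = simulate_surveys(roster, truth, seed=rep_seed)
            deltas, _ = delta_from_baseline(surveys)
            wide = deltas[deltas.scale.isin(["BorgRPE", "OmniRPE"])].pivot_table(
                index=["subject_id", "timepoint"], columns="scale", values="delta"
            ).dropna()
            r, _, _ = spearman_correlation(wide.BorgRPE, wide.OmniRPE)
            vals.append(r)
        vals = np.asarray(vals)
        rows.append(
            {
                "programmed_rho": float(rho),
                "mean_spearman": float(vals.mean()),
                "mc_se": float(vals.std(ddof=1) / np.sqrt(n_reps)),
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)


def cr10_slope_null_correlation(
    n_reps: int = 3,
    n_per_group: int = 4,
    seed: int = 0,
    schedule: ShiftSchedule | None = None,
) -> dict:
    """Correlation between b_time and the CR10 change when they are decoupled.

    The generator draws the CR10 ratings from latent exertion and the EMG
    slope from its own parameters, independently; the estimated correlation
    across subject-sides must therefore be consistent with zero.
    """
    schedule = schedule or short_schedule()
    vals = []
    n_pairs = 0
    for rep in range(n_reps):
        rep_seed = (seed * 49957 + rep) % (2**31)
        roster = simulate_cohort(CohortSpec(n_per_group=n_per_group, seed=rep_seed))
        truth = default_ground_truth(roster, seed=rep_seed, emg_slope_sd=0.01)
        slopes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for sid in roster.subject_id:
                for side in ("left", "right"):
                    rec = simulate_emg(sid, side, schedule, truth, seed=rep_seed)
                    feats = window_features(bandpass(rec), schedule)
                    fit = fit_fatigue_slope(feats)
                    slopes.append(
                        {"subject_id": sid, "side": side, "b_time": fit.b_time}
                    )
        slopes = pd.DataFrame(slopes)
        surveys = simulate_surveys(roster, truth, seed=rep_seed)
        cr10 = cr10_shift_change(surveys, roster)
        merged = slopes.merge(cr10, on=["subject_id", "side"]).dropna(
            subset=["b_time", "cr10_change"]
        )
        r, _, n = pearson_correlation(merged.b_time, merged.cr10_change)
        vals.append(r)
        n_pairs = n
    vals = np.asarray(vals)
    null_se = 1.0 / np.sqrt(max(n_pairs - 3, 1)) / np.sqrt(n_reps)
    return {
        "mean_correlation": float(vals.mean()),
        "null_se": float(null_se),
        "n_pairs": int(n_pairs),
        "n_reps": n_reps,
    }
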