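"""The statistical battery linking direct and subjective effort measures.

Direct measures: %HRR per survey period (metabolic load) and the per
subject-side MDF fatigue slope b_time. Subjective measures: Borg RPE and
Omni RPE deltas from baseline, and the end-of-shift CR10 change. The battery
runs unadjusted Pearson correlations, confounder-adjusted linear regressions
(harvesting method, work period, muscle side), analyses stratified by method
or by period, Spearman rank correlation between the two RPE scales, a
two-way ANOVA with Tukey HSD on %HRR, and Kruskal-Wallis with Dunn pairwise
rank-sum post hocs on the rating deltas. Confidence level is fixed at 95%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class UndefinedStatisticError(ValueError):
    """Raised when a correlation is undefined (zero variance)."""


def _missing_result(
    analysis_id: str,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
    stratum: str = "all",
    n: int = 0,
) -> "AssociationResult":
    nan = float("nan")
    return AssociationResult(
        analysis_id=analysis_id,
        outcome=outcome,
        predictor=predictor,
        covariates=covariates,
        stratum=stratum,
        estimate=nan,
        ci_low=nan,
        ci_high=nan,
        p_value=nan,
        n=n,
        missing=True,
    )


@dataclass(frozen=True)
class AssociationResult:
    """One estimate from the correlation/regression battery."""

    analysis_id: str
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    stratum: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    kind: str = "correlation"  # or "regression"
    missing: bool = False

    def as_row(self) -> dict:
        d = self.__dict__.copy()
        d["covariates"] = "+".join(self.covariates)
        return d


@dataclass(frozen=True)
class GroupEffectResult:
    """Omnibus test plus pairwise post hocs for one factor."""

    outcome: str
    factor: str
    method: str  # "anova_tukey" or "kruskal_dunn"
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# elementary correlations


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Product-moment correlation with the two-sided t-based p-value."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue), len(x)


def spearman_correlation(x, y) -> tuple[float, float, int]:
    """Rank (mid-rank for ties) correlation with its two-sided p-value."""
    x, y = _paired(x, y)
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    r = stats.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue), len(x)


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    return x, y


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def correlation_result(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    *,
    method: str = "pearson",
    stratum: str = "all",
    analysis_id: str | None = None,
) -> AssociationResult:
    """Unadjusted correlation between two columns, packaged with a Fisher CI."""
    fn = pearson_correlation if method == "pearson" else spearman_correlation
    r, p, n = fn(df[outcome], df[predictor])
    lo, hi = _fisher_ci(r, n)
    return AssociationResult(
        analysis_id=analysis_id or f"{method}:{outcome}~{predictor}:{stratum}",
        outcome=outcome,
        predictor=predictor,
        covariates=(),
        stratum=stratum,
        estimate=r,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        n=n,
        kind="correlation",
    )


# ---------------------------------------------------------------------------
# adjusted and stratified regressions


def adjusted_regression(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = ("period", "group"),
    *,
    stratum: str = "all",
    analysis_id: str | None = None,
) -> AssociationResult:
    """OLS of the outcome on the predictor plus categorical confounders.

    Categorical covariates get treatment coding with the alphabetically first
    level as reference. Reports the predictor coefficient with its 95% CI.
    """
    cols = [outcome, predictor, *covariates]
    data = df[cols].dropna().copy()
    if len(data) < len(covariates) + 3:
        raise ValueError("too few complete cases for the adjusted model")
    terms = [predictor] + [
        f"C({c})" if not np.issubdtype(data[c].dtype, np.number) else c
        for c in covariates
    ]
    fit = smf.ols(f"{outcome} ~ {' + '.join(terms)}", data=data).fit()
    ci = fit.conf_int(alpha=0.05).loc[predictor]
    return AssociationResult(
        analysis_id=analysis_id
        or f"ols:{outcome}~{predictor}|{'+'.join(covariates)}:{stratum}",
        outcome=outcome,
        predictor=predictor,
        covariates=tuple(covariates),
        stratum=stratum,
        estimate=float(fit.params[predictor]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues[predictor]),
        n=int(fit.nobs),
        kind="regression",
    )


def stratified_association(
    df: pd.DataFrame,
    outcome: str,
    predictor: str,
    *,
    by: str,
    adjust: tuple[str, ...] = (),
    min_n: int = 3,
) -> list[AssociationResult]:
    """One association per stratum of ``by`` (adjusted if ``adjust`` given).

    Strata with fewer than ``min_n`` complete cases are reported as missing
    records, never silently dropped.
    """
    out: list[AssociationResult] = []
    for level, sub in df.groupby(by, sort=True):
        n_complete = sub[[outcome, predictor]].dropna().shape[0]
        stratum = f"{by}={level}"
        if n_complete < min_n:
            out.append(
                _missing_result(
                    f"strat:{outcome}~{predictor}:{stratum}",
                    outcome, predictor, tuple(adjust), stratum, n_complete,
                )
            )
            continue
        usable_adjust = tuple(c for c in adjust if sub[c].nunique() > 1)
        try:
            if usable_adjust:
                out.append(
                    adjusted_regression(
                        sub, outcome, predictor, usable_adjust, stratum=stratum
                    )
                )
            else:
                out.append(
                    correlation_result(sub, outcome, predictor, stratum=stratum)
                )
        except (ValueError, UndefinedStatisticError):
            out.append(
                _missing_result(
                    f"strat:{outcome}~{predictor}:{stratum}",
                    outcome, predictor, usable_adjust, stratum, n_complete,
                )
            )
    return out


# ---------------------------------------------------------------------------
# group / time effects


def group_time_effects_hrr(
    hrr: pd.DataFrame,
    outcome: str = "hrr_sqrt",
    *,
    group_col: str = "group",
    period_col: str = "period",
    anova_type: int = 1,
) -> list[GroupEffectResult]:
    """Two-way ANOVA (harvesting group, work period) with Tukey HSD on groups.

    Sequential (type-I) sums of squares by default, matching the classic
    ``anova(lm(...))`` workflow; Tukey pairwise comparisons are reported for
    the group factor and, when more than two periods exist, for period too.
    """
    data = hrr[[outcome, group_col, period_col]].dropna().copy()
    if data[group_col].nunique() < 2 or data[period_col].nunique() < 2:
        raise ValueError("need at least 2 groups and 2 periods")
    fit = smf.ols(
        f"{outcome} ~ C({group_col}) + C({period_col})", data=data
    ).fit()
    table = anova_lm(fit, typ=anova_type)
    results = []
    for factor, label in ((group_col, "harvesting_method"), (period_col, "work_period")):
        row = table.loc[f"C({factor})"]
        tk = pairwise_tukeyhsd(data[outcome], data[factor])
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"meandiff": "estimate", "p-adj": "p_value"}
        )
        results.append(
            GroupEffectResult(
                outcome=outcome,
                factor=label,
                method="anova_tukey",
                omnibus_stat=float(row["F"]),
                omnibus_p=float(row["PR(>F)"]),
                pairwise=pairwise,
            )
        )
    return results


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Returns (0, 1) when every observation is tied (no rank variance).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    samples = [values[labels == g] for g in pd.unique(labels)]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


def dunn_test(values, groups, *, adjust: str | None = None) -> pd.DataFrame:
    """Dunn's pairwise rank-sum z-tests after a Kruskal-Wallis omnibus.

    The z statistic for groups i, j compares mean ranks using the tie-corrected
    variance ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t)`` over tie groups. Unadjusted two-sided p-values by
    default; ``adjust="holm"`` applies a Holm step-down correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    ranks = stats.rankdata(values)
    N = values.size
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    mean_rank = {g: ranks[labels == g].mean() for g in levels}
    n_g = {g: int((labels == g).sum()) for g in levels}
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        se = np.sqrt(var_term * (1.0 / n_g[g1] + 1.0 / n_g[g2]))
        z = 0.0 if se == 0 else (mean_rank[g1] - mean_rank[g2]) / se
        p = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": g1, "group2": g2, "z": float(z), "p_value": float(p)})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(-np.abs(out.z.to_numpy()))
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out.p_value.iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_adjusted"] = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def group_effects_nonparametric(
    df: pd.DataFrame,
    value_col: str,
    factor_col: str,
    *,
    outcome_label: str | None = None,
    factor_label: str | None = None,
    adjust: str | None = None,
) -> GroupEffectResult:
    """Kruskal-Wallis omnibus plus Dunn pairwise post hocs for one factor.

    Empty groups (all-NaN) are excluded with a warning-free drop via
    ``dropna``; no multiplicity adjustment by default.
    """
    data = df[[value_col, factor_col]].dropna()
    counts = data.groupby(factor_col).size()
    keep = counts[counts > 0].index
    data = data[data[factor_col].isin(keep)]
    h, p = kruskal_wallis(data[value_col], data[factor_col])
    pairwise = dunn_test(data[value_col], data[factor_col], adjust=adjust)
    return GroupEffectResult(
        outcome=outcome_label or value_col,
        factor=factor_label or factor_col,
        method="kruskal_dunn",
        omnibus_stat=h,
        omnibus_p=p,
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# the full battery


def overall_effort_table(
    hrr: pd.DataFrame, deltas: pd.DataFrame
) -> pd.DataFrame:
    """Join %HRR per subject-period with RPE deltas into one analysis frame.

    Columns: subject_id, group, period, hrr, hrr_sqrt, BorgRPE_delta,
    OmniRPE_delta. The join key is the period label: T1/T3 heart-rate windows
    cover the work bout immediately preceding the survey of the same label.
    """
    wide = (
        deltas[deltas.scale.isin(["BorgRPE", "OmniRPE"])]
        .pivot_table(
            index=["subject_id", "timepoint"], columns="scale", values="delta"
        )
        .rename(columns={"BorgRPE": "BorgRPE_delta", "OmniRPE": "OmniRPE_delta"})
        .reset_index()
        .rename(columns={"timepoint": "period"})
    )
    return hrr.merge(wide, on=["subject_id", "period"], how="left")


def local_discomfort_table(
    slopes: pd.DataFrame, cr10_changes: pd.DataFrame, roster: pd.DataFrame
) -> pd.DataFrame:
    """Join per-subject-side fatigue slopes with the CR10 shift change."""
    out = slopes.merge(
        cr10_changes[["subject_id", "side", "dominance", "cr10_change"]],
        on=["subject_id", "side"],
        how="left",
    )
    return out.merge(roster[["subject_id", "group"]], on="subject_id", how="left")


def association_battery(
    hrr: pd.DataFrame,
    deltas: pd.DataFrame,
    slopes: pd.DataFrame,
    cr10_changes: pd.DataFrame,
    roster: pd.DataFrame,
    *,
    outcome_scale: str = "hrr_sqrt",
) -> dict:
    """Run the complete direct-vs-subjective analysis set.

    Returns a dict with the tidy association results frame, the group/time
    effect results, and the RPE-vs-RPE Spearman correlation.
    """
    overall = overall_effort_table(hrr, deltas)
    local = local_discomfort_table(slopes, cr10_changes, roster)
    results: list[AssociationResult] = []

    def guarded(fn, analysis_id, outcome, predictor, covariates=()):
        try:
            results.append(fn())
        except (ValueError, UndefinedStatisticError):
            results.append(
                _missing_result(analysis_id, outcome, predictor, covariates)
            )

    for predictor in ("BorgRPE_delta", "OmniRPE_delta"):
        guarded(
            lambda: correlation_result(overall, outcome_scale, predictor),
            f"pearson:{outcome_scale}~{predictor}:all", outcome_scale, predictor,
        )
        guarded(
            lambda: adjusted_regression(
                overall, outcome_scale, predictor, ("period", "group")
            ),
            f"ols:{outcome_scale}~{predictor}|period+group:all",
            outcome_scale, predictor, ("period", "group"),
        )
        results.extend(
            stratified_association(
                overall, outcome_scale, predictor, by="group", adjust=("period",)
            )
        )
        results.extend(
            stratified_association(overall, outcome_scale, predictor, by="period")
        )

    # local discomfort: fatigue slope vs CR10 change
    guarded(
        lambda: correlation_result(local, "b_time", "cr10_change"),
        "pearson:b_time~cr10_change:all", "b_time", "cr10_change",
    )
    guarded(
        lambda: adjusted_regression(
            local, "b_time", "cr10_change", ("group", "dominance")
        ),
        "ols:b_time~cr10_change|group+dominance:all",
        "b_time", "cr10_change", ("group", "dominance"),
    )

    # between the two subjective overall-effort scales
    pair = overall[["BorgRPE_delta", "OmniRPE_delta"]].dropna()
    try:
        rpe_spearman = correlation_result(
            pair, "BorgRPE_delta", "OmniRPE_delta", method="spearman",
            analysis_id="spearman:BorgRPE_delta~OmniRPE_delta",
        )
    except (ValueError, UndefinedStatisticError):
        rpe_spearman = _missing_result(
            "spearman:BorgRPE_delta~OmniRPE_delta",
            "BorgRPE_delta", "OmniRPE_delta",
        )
    results.append(rpe_spearman)

    try:
        group_effects = group_time_effects_hrr(hrr, outcome_scale)
    except ValueError:
        group_effects = []
    delta_effects = []
    for scale in ("BorgRPE", "OmniRPE"):
        sub = deltas[deltas.scale == scale].merge(
            roster[["subject_id", "group"]], on="subject_id"
        )
        for factor, label in (("group", "harvesting_method"), ("timepoint", "work_period")):
            delta_effects.append(
                group_effects_nonparametric(
                    sub, "delta", factor,
                    outcome_label=f"{scale}_delta", factor_label=label,
                )
            )
    cr = cr10_changes.merge(roster[["subject_id", "group"]], on="subject_id")
    for factor, label in (("group", "harvesting_method"), ("dominance", "side")):
        delta_effects.append(
            group_effects_nonparametric(
                cr, "cr10_change", factor,
                outcome_label="CR10_change", factor_label=label,
            )
        )

    return {
        "associations": pd.DataFrame([r.as_row() for r in results]),
        "group_effects": group_effects + delta_effects,
        "rpe_spearman": rpe_spearman,
        "overall_table": overall,
        "local_table": local,
    }
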