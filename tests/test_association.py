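
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ergofield.association import (
    UndefinedStatisticError,
    adjusted_regression,
    correlation_result,
    dunn_test,
    group_effects_nonparametric,
    group_time_effects_hrr,
    kruskal_wallis,
    pearson_correlation,
    spearman_correlation,
    stratified_association,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_matches_covariance_formula(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r, _, _ = pearson_correlation(x, y)
        oracle = np.mean((x - x.mean()) * (y - y.mean())) / (
            x.std(ddof=0) * y.std(ddof=0)
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_type_one_error_calibrated(self, rng):
        rejections = sum(
            pearson_correlation(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
            for _ in range(200)
        )
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rejections / 200 - 0.05) < 2 * se + 1e-9


class TestSpearman:
    def test_monotone_pairs(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        rho, _, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho_rev, _, _ = spearman_correlation(x, -(x**3))
        assert rho_rev == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=30).astype(float)
        rho, _, _ = spearman_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestAdjustedRegression:
    def _frame(self, rng, n=60, beta=0.0):
        period = rng.choice(["T1", "T2", "T3"], size=n)
        group = rng.choice(["Ground", "Ladder", "Platform"], size=n)
        period_eff = pd.Series(period).map({"T1": 0.3, "T2": 0.0, "T3": 0.4})
        x = rng.normal(size=n) + 2 * (period == "T3")
        y = beta * x + period_eff.to_numpy() + 0.1 * rng.normal(size=n)
        return pd.DataFrame(
            {"hrr_sqrt": y, "delta": x, "period": period, "group": group}
        )

    def test_constant_covariates_equal_unadjusted(self, rng):
        df = self._frame(rng)
        df["group"] = "Ground"
        res = adjusted_regression(df, "hrr_sqrt", "delta", ("group",))
        slope = stats.linregress(df.delta, df.hrr_sqrt).slope
        assert res.estimate == pytest.approx(slope, abs=1e-10)

    def test_null_effect_covered_by_ci(self, rng):
        hits = 0
        for _ in range(100):
            df = self._frame(rng, beta=0.0)
            res = adjusted_regression(df, "hrr_sqrt", "delta", ("period", "group"))
            hits += res.ci_low <= 0.0 <= res.ci_high
        assert hits >= 90  # 95% CI coverage within binomial slack

    def test_simpson_style_sign_flip_matches_normal_equations(self, rng):
        # strong positive period confounding: unadjusted slope positive,
        # within-period relationship negative
        n = 90
        period = np.repeat(["T1", "T2", "T3"], n // 3)
        shift = pd.Series(period).map({"T1": 0.0, "T2": 2.0, "T3": 4.0}).to_numpy()
        x = shift + rng.normal(scale=0.4, size=n)
        y = shift - 0.5 * (x - shift) + 0.05 * rng.normal(size=n)
        df = pd.DataFrame(
            {"hrr_sqrt": y, "delta": x, "period": period, "group": "Ground"}
        )
        unadj = stats.linregress(df.delta, df.hrr_sqrt).slope
        res = adjusted_regression(df, "hrr_sqrt", "delta", ("period",))
        assert unadj > 0 > res.estimate
        X = np.column_stack(
            [np.ones(n), x, (period == "T2").astype(float), (period == "T3").astype(float)]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.estimate == pytest.approx(beta[1], abs=1e-9)

    def test_affine_predictor_rescaling(self, rng):
        df = self._frame(rng, beta=0.4)
        res1 = adjusted_regression(df, "hrr_sqrt", "delta", ("period",))
        df2 = df.assign(delta=3.0 * df.delta + 7.0)
        res2 = adjusted_regression(df2, "hrr_sqrt", "delta", ("period",))
        assert res2.estimate == pytest.approx(res1.estimate / 3.0, rel=1e-9)
        assert res2.p_value == pytest.approx(res1.p_value, abs=1e-12)


class TestStratified:
    def _frame(self, rng, effects):
        rows = []
        for grp, eff in effects.items():
            x = rng.normal(size=30)
            y = eff * x + 0.3 * rng.normal(size=30)
            rows.append(
                pd.DataFrame(
                    {"y": y, "x": x, "group": grp,
                     "period": rng.choice(["T1", "T2", "T3"], size=30)}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_single_stratum_equals_unstratified(self, rng):
        df = self._frame(rng, {"Ground": 0.5})
        strat = stratified_association(df, "y", "x", by="group")
        full = correlation_result(df, "y", "x")
        assert len(strat) == 1
        assert strat[0].estimate == pytest.approx(full.estimate)

    def test_recovers_per_stratum_effect_ordering(self, rng):
        df = self._frame(rng, {"Ground": 0.8, "Ladder": 0.8, "Platform": 0.0})
        strat = {
            r.stratum: r.estimate
            for r in stratified_association(df, "y", "x", by="group")
        }
        assert strat["group=Ground"] > strat["group=Platform"]
        assert strat["group=Ladder"] > strat["group=Platform"]

    def test_small_stratum_reported_missing(self, rng):
        df = self._frame(rng, {"Ground": 0.5})
        df = pd.concat(
            [df, pd.DataFrame({"y": [1.0], "x": [1.0], "group": "Tiny",
                               "period": ["T1"]})],
            ignore_index=True,
        )
        strat = stratified_association(df, "y", "x", by="group")
        tiny = [r for r in strat if r.stratum == "group=Tiny"][0]
        assert tiny.missing and np.isnan(tiny.estimate)


def brute_force_kruskal(values, labels):
    """H statistic straight from mid-ranks with the tie correction."""
    values = np.asarray(values, float)
    ranks = stats.rankdata(values)
    N = len(values)
    h = 0.0
    for g in np.unique(labels):
        rg = ranks[labels == g]
        h += rg.sum() ** 2 / len(rg)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(values, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / tie


def brute_force_dunn_z(values, labels, g1, g2):
    values = np.asarray(values, float)
    ranks = stats.rankdata(values)
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    var = (N * (N + 1) / 12.0) - np.sum(counts**3 - counts) / (12.0 * (N - 1))
    m1, m2 = ranks[labels == g1].mean(), ranks[labels == g2].mean()
    n1, n2 = (labels == g1).sum(), (labels == g2).sum()
    return (m1 - m2) / np.sqrt(var * (1 / n1 + 1 / n2))


class TestRankTests:
    def test_kruskal_matches_brute_force_with_ties(self, rng):
        values = rng.integers(0, 6, size=36).astype(float)
        labels = np.repeat(np.array(["a", "b", "c"]), 12)
        h, _ = kruskal_wallis(values, labels)
        assert h == pytest.approx(brute_force_kruskal(values, labels), abs=1e-10)

    def test_all_tied_zero_statistic(self):
        h, p = kruskal_wallis(np.ones(12), np.repeat(["a", "b"], 6))
        assert h == 0.0 and p == 1.0

    def test_dunn_matches_brute_force(self, rng):
        values = rng.integers(0, 8, size=30).astype(float)
        labels = np.repeat(np.array(["a", "b", "c"]), 10)
        out = dunn_test(values, labels)
        for _, row in out.iterrows():
            z = brute_force_dunn_z(values, labels, row.group1, row.group2)
            assert row.z == pytest.approx(z, abs=1e-10)
            assert row.p_value == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_holm_adjustment_monotone(self, rng):
        values = np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10),
                                 rng.normal(0, 1, 10)])
        labels = np.repeat(np.array(["a", "b", "c"]), 10)
        out = dunn_test(values, labels, adjust="holm")
        assert (out.p_adjusted >= out.p_value - 1e-15).all()
        assert (out.p_adjusted <= 1.0).all()

    def test_shifted_group_has_smallest_pairwise_p(self, rng):
        hits = 0
        for _ in range(50):
            values = np.concatenate(
                [rng.normal(0, 1, 8), rng.normal(0, 1, 8), rng.normal(2.5, 1, 8)]
            )
            labels = np.repeat(np.array(["a", "b", "c"]), 8)
            res = group_effects_nonparametric(
                pd.DataFrame({"v": values, "g": labels}), "v", "g"
            )
            pw = res.pairwise
            involves_c = pw.apply(lambda r: "c" in (r.group1, r.group2), axis=1)
            hits += pw[involves_c].p_value.min() <= pw.p_value.min() + 1e-15
        assert hits >= 45


class TestGroupTimeAnova:
    def _hrr(self, rng, shift=0.0):
        rows = []
        for grp in ("Ground", "Ladder", "Platform"):
            for period in ("T1", "T2", "T3"):
                mu = 0.5 + (shift if grp == "Ladder" else 0.0)
                mu += {"T1": 0.05, "T2": -0.1, "T3": 0.08}[period]
                for _ in range(8):
                    rows.append(
                        {"group": grp, "period": period,
                         "hrr_sqrt": mu + 0.08 * rng.normal()}
                    )
        return pd.DataFrame(rows)

    def test_two_groups_single_tukey_pair(self, rng):
        df = self._hrr(rng)
        df = df[df.group != "Platform"]
        res = group_time_effects_hrr(df)
        group_res = [r for r in res if r.factor == "harvesting_method"][0]
        assert len(group_res.pairwise) == 1

    def test_shifted_group_detected_with_power(self, rng):
        detected = 0
        for _ in range(40):
            df = self._hrr(rng, shift=0.2)
            res = group_time_effects_hrr(df)
            g = [r for r in res if r.factor == "harvesting_method"][0]
            ladder = g.pairwise[
                (g.pairwise.group1 == "Ladder") | (g.pairwise.group2 == "Ladder")
            ]
            detected += (ladder.p_value < 0.05).all()
        assert detected / 40 > 0.8

    def test_anova_needs_two_levels(self, rng):
        df = self._hrr(rng)
        with pytest.raises(ValueError):
            group_time_effects_hrr(df[df.group == "Ground"])
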