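"""Group inference: ANOVA (raw and from summaries), post hoc tests, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from backmap.stats import (
    GroupSamples,
    SummaryStats,
    anova_from_summary,
    duncan_posthoc,
    games_howell,
    oneway_anova,
    run_group_report,
    shapiro_wilk,
    spearman,
    variance_homogeneity,
    welch_anova,
    welch_from_summary,
)

pingouin = pytest.importorskip("pingouin")


def exact_moments_sample(mean, sd, n, rng):
    """A sample with exactly the requested mean and (ddof=1) SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


def random_samples(rng, k=None, metric="m"):
    k = k or rng.integers(2, 6)
    groups = {
        f"g{i}": rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=rng.integers(3, 16))
        for i in range(k)
    }
    return GroupSamples(metric=metric, groups=groups)


class TestShapiroWilk:
    def test_normal_quantiles_high_w(self):
        q = sps.norm.ppf(np.linspace(0.02, 0.98, 30))
        w, _ = shapiro_wilk(q)
        assert w > 0.99

    def test_bimodal_rejected(self, rng):
        x = np.concatenate([rng.normal(-5, 0.1, 10), rng.normal(5, 0.1, 10)])
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestVarianceGate:
    def test_identical_groups_equal(self, rng):
        x = rng.normal(size=10)
        s = GroupSamples("m", {"a": x, "b": x + 1.0})
        _, _, equal = variance_homogeneity(s)
        assert equal

    def test_large_variance_ratio_detected(self, rng):
        s = GroupSamples("m", {"a": rng.normal(0, 1, 20), "b": rng.normal(0, 10, 20)})
        _, _, equal = variance_homogeneity(s)
        assert not equal

    def test_shift_invariance(self, rng):
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(0, 2, 12)}
        stat1, _, _ = variance_homogeneity(GroupSamples("m", groups))
        stat2, _, _ = variance_homogeneity(
            GroupSamples("m", {k: v + 100.0 for k, v in groups.items()})
        )
        assert stat1 == pytest.approx(stat2)


class TestOnewayAnova:
    def test_identical_means_f_zero(self):
        s = GroupSamples("m", {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = oneway_anova(s)
        assert res.F == pytest.approx(0.0)
        assert res.eta_squared == pytest.approx(0.0)

    def test_matches_scipy(self, rng):
        for _ in range(20):
            s = random_samples(rng)
            res = oneway_anova(s)
            f_ref, p_ref = sps.f_oneway(*s.groups.values())
            assert res.F == pytest.approx(f_ref, rel=1e-10)
            assert res.p == pytest.approx(p_ref, rel=1e-8)

    def test_two_groups_equals_t_squared(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 11)
        res = oneway_anova(GroupSamples("m", {"a": a, "b": b}))
        t, _ = sps.ttest_ind(a, b)
        assert res.F == pytest.approx(t**2, rel=1e-10)

    def test_eta_monotone_in_separation(self, rng):
        base = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10), "c": rng.normal(0, 1, 10)}
        etas = []
        for shift in [0.0, 1.0, 2.0, 4.0]:
            g = dict(base)
            g["c"] = base["c"] + shift
            etas.append(oneway_anova(GroupSamples("m", g)).eta_squared)
        assert all(x < y for x, y in zip(etas, etas[1:]))
        assert all(0.0 <= e <= 1.0 for e in etas)


class TestFromSummaryIdentity:
    def test_summary_identity_classic(self, rng):
        """anova_from_summary(summaries(X)) == oneway_anova(X), the central oracle."""
        for _ in range(30):
            s = random_samples(rng)
            raw = oneway_anova(s)
            summ = anova_from_summary(SummaryStats.from_samples(s))
            assert summ.F == pytest.approx(raw.F, rel=1e-10)
            assert summ.eta_squared == pytest.approx(raw.eta_squared, rel=1e-10)
            assert summ.p == pytest.approx(raw.p, rel=1e-8)

    def test_summary_identity_welch(self, rng):
        for _ in range(30):
            s = random_samples(rng)
            raw = welch_anova(s)
            summ = welch_from_summary(SummaryStats.from_samples(s))
            assert summ.F == pytest.approx(raw.F, rel=1e-10)
            assert summ.df2 == pytest.approx(raw.df2, rel=1e-10)

    def test_identical_means_zero_f(self):
        summ = SummaryStats(labels=("a", "b", "c"), means=(5.0, 5.0, 5.0),
                            sds=(1.0, 2.0, 1.5), ns=(5, 6, 7))
        assert anova_from_summary(summ).F == pytest.approx(0.0)
        assert welch_from_summary(summ).F == pytest.approx(0.0)

    def test_two_group_summary_equals_pooled_t_squared(self, rng):
        a = exact_moments_sample(0.0, 1.2, 9, rng)
        b = exact_moments_sample(1.5, 0.8, 12, rng)
        summ = SummaryStats(labels=("a", "b"), means=(0.0, 1.5), sds=(1.2, 0.8), ns=(9, 12))
        t, _ = sps.ttest_ind(a, b)
        assert anova_from_summary(summ).F == pytest.approx(t**2, rel=1e-9)

    def test_zero_ssw_flagged_infinite(self):
        summ = SummaryStats(labels=("a", "b"), means=(0.0, 1.0), sds=(0.0, 0.0), ns=(5, 5))
        res = anova_from_summary(summ)
        assert np.isinf(res.F) and res.p == 0.0


class TestWelchAnova:
    def test_equal_means_f_near_zero(self):
        s = GroupSamples("m", {"a": [1.0, 2.0, 3.0], "b": [0.5, 2.0, 3.5]})
        assert welch_anova(s).F == pytest.approx(0.0)

    def test_balanced_homoscedastic_limit(self, rng):
        """Equal n, equal sample variances: Welch F converges to classic F
        (the finite-sample correction 1+b shrinks as 1/n)."""
        gaps = []
        for n in [10, 100, 10000]:
            a = rng.normal(0, 1, n)
            s = GroupSamples("m", {"a": a, "b": a + 1.0, "c": a - 0.5})
            w, c = welch_anova(s).F, oneway_anova(s).F
            gaps.append(abs(w - c) / c)
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3

    def test_matches_pingouin(self, rng):
        for _ in range(50):
            s = random_samples(rng, k=4)
            res = welch_anova(s)
            df = pd.DataFrame(
                [(g, v) for g, vals in s.groups.items() for v in vals],
                columns=["group", "value"],
            )
            ref = pingouin.welch_anova(dv="value", between="group", data=df)
            assert res.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
            assert res.df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-6)

    def test_zero_variance_rejected(self):
        s = GroupSamples("m", {"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="variance"):
            welch_anova(s)


class TestDuncan:
    def test_null_no_separation(self, rng):
        x = rng.normal(size=10)
        s = GroupSamples("m", {"a": x, "b": x + 0.01, "c": x - 0.01})
        assert not any(r.significant for r in duncan_posthoc(s))

    def test_widely_separated_pair_found(self, rng):
        s = GroupSamples("m", {"a": rng.normal(0, 1, 10), "b": rng.normal(10, 1, 10)})
        res = duncan_posthoc(s)
        assert len(res) == 1 and res[0].significant and res[0].p < 0.001

    def test_two_group_p_matches_studentized_range(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1.2, 1, 10)
        s = GroupSamples("m", {"a": a, "b": b})
        res = duncan_posthoc(s)[0]
        msw = (np.var(a, ddof=1) + np.var(b, ddof=1)) / 2
        q = abs(a.mean() - b.mean()) / np.sqrt(msw / 10)
        assert res.p == pytest.approx(float(sps.studentized_range.sf(q, 2, 18)), rel=1e-9)

    def test_all_pairs_reported_with_valid_p(self, rng):
        s = random_samples(rng, k=4)
        res = duncan_posthoc(s)
        assert len(res) == 6
        assert all(0.0 <= r.p <= 1.0 for r in res)


class TestGamesHowell:
    def test_identical_groups_p_near_one(self, rng):
        x = rng.normal(size=12)
        s = GroupSamples("m", {"a": x, "b": x, "c": x})
        assert all(r.p > 0.99 for r in games_howell(s))

    def test_matches_pingouin(self, rng):
        for _ in range(20):
            s = random_samples(rng, k=4)
            res = {tuple(sorted(r.pair)): r.p for r in games_howell(s)}
            df = pd.DataFrame(
                [(g, v) for g, vals in s.groups.items() for v in vals],
                columns=["group", "value"],
            )
            ref = pingouin.pairwise_gameshowell(dv="value", between="group", data=df)
            for _, row in ref.iterrows():
                key = tuple(sorted((row["A"], row["B"])))
                assert res[key] == pytest.approx(float(row["pval"]), abs=1e-3)

    def test_zero_variance_pair_rejected(self):
        s = GroupSamples("m", {"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError, match="zero variance"):
            games_howell(s)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]).rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        r = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.rho == pytest.approx(0.6)

    def test_constant_input_undefined(self):
        r = spearman([1.0, 1.0, 1.0], [1, 2, 3])
        assert np.isnan(r.rho)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = spearman(x, y).rho
        r2 = spearman(np.exp(x), y**3).rho if np.all(y == y) else None
        assert r1 == pytest.approx(spearman(np.exp(x), y).rho)


class TestGroupReport:
    def _metrics(self, rng, n_per=6):
        rows = []
        for variable in ["volume DM", "area DM"]:
            for g in ["A", "B", "C"]:
                for i in range(n_per):
                    rows.append({"subject_id": f"{g}{i}", "group": g,
                                 "variable": variable, "value": rng.normal()})
        return pd.DataFrame(rows)

    def test_row_count_matches_variables(self, rng):
        rep = run_group_report(self._metrics(rng))
        assert len(rep.omnibus) == 2
        assert set(rep.omnibus["variable"]) == {"volume DM", "area DM"}

    def test_reported_p_is_unadjusted(self, rng):
        """No multiplicity adjustment anywhere: report p equals the raw omnibus p."""
        metrics = self._metrics(rng)
        rep = run_group_report(metrics, variance_gate="classic")
        for _, row in rep.omnibus.iterrows():
            sub = metrics[metrics["variable"] == row["variable"]]
            s = GroupSamples("m", {g: v["value"].to_numpy() for g, v in sub.groupby("group")})
            assert row["p"] == pytest.approx(oneway_anova(s).p, rel=1e-12)

    def test_small_group_dropped_and_skipped(self, rng):
        df = pd.DataFrame(
            [
                {"subject_id": "a1", "group": "A", "variable": "v", "value": 1.0},
                {"subject_id": "a2", "group": "A", "variable": "v", "value": 2.0},
                {"subject_id": "b1", "group": "B", "variable": "v", "value": 3.0},
            ]
        )
        rep = run_group_report(df)
        assert rep.skipped and rep.skipped[0][0] == "v"
        assert len(rep.omnibus) == 0

    def test_gate_selects_welch_under_heteroscedasticity(self, rng):
        rows = []
        for g, sd in [("A", 0.5), ("B", 8.0), ("C", 0.5)]:
            for i in range(15):
                rows.append({"subject_id": f"{g}{i}", "group": g, "variable": "v",
                             "value": rng.normal(0, sd)})
        rep = run_group_report(pd.DataFrame(rows))
        assert rep.omnibus["method"].iloc[0] == "welch"
        assert set(rep.posthoc["method"]) == {"games_howell"}
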