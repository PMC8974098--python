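import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from lifelines.statistics import logrank_test

from _oracles import bh_stepup, km_no_censoring, logrank_hand, mw_enumerate_p
from depth2.cohort_stats import (
    km_logrank,
    kruskal_wallis,
    mannwhitney_one_sided,
    median_split,
    spearman_screen,
)


def _series(vals, prefix="S"):
    return pd.Series(vals, index=[f"{prefix}{i}" for i in range(len(vals))])


class TestMedianSplit:
    def test_even_split_without_ties(self):
        labels = median_split(_series([1.0, 2.0, 3.0, 4.0]))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_are_excluded(self):
        labels = median_split(_series([1.0, 2.0, 2.0, 3.0]))
        assert sorted(labels.unique()) == ["high", "low"]
        assert len(labels) == 2
        assert labels["S0"] == "low" and labels["S3"] == "high"

    def test_all_identical_scores_is_error(self):
        with pytest.raises(ValueError, match="median split impossible"):
            median_split(_series([5.0] * 4))

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match=">= 4"):
            median_split(_series([1.0, 2.0, 3.0]))


class TestSpearmanScreen:
    def test_perfect_monotone_and_antitone(self):
        x = _series([1.0, 2.0, 3.0])
        ys = pd.DataFrame(
            {"up": [2.0, 4.0, 6.0], "down": [6.0, 4.0, 2.0]}, index=x.index
        )
        res = spearman_screen(x, ys).set_index("variable")
        assert res.loc["up", "rho"] == pytest.approx(1.0)
        assert res.loc["down", "rho"] == pytest.approx(-1.0)

    def test_bh_fdr_matches_stepup_rule(self, rng):
        x = _series(list(rng.normal(size=12)))
        ys = pd.DataFrame(
            rng.normal(size=(12, 6)), index=x.index,
            columns=[f"v{i}" for i in range(6)],
        )
        res = spearman_screen(x, ys)
        want = bh_stepup(res["p_value"].tolist())
        np.testing.assert_allclose(res["fdr"], want, rtol=1e-12)
        assert (res["fdr"] >= res["p_value"] - 1e-15).all()
        assert (res["fdr"] <= 1.0).all()

    def test_constant_column_flagged_and_excluded_from_family(self, rng):
        x = _series(list(rng.normal(size=8)))
        ys = pd.DataFrame(
            {"flat": [1.0] * 8, "ok": list(rng.normal(size=8))}, index=x.index
        )
        res = spearman_screen(x, ys).set_index("variable")
        assert np.isnan(res.loc["flat", "rho"])
        assert np.isnan(res.loc["flat", "fdr"])
        # family of one defined test: fdr equals raw p
        assert res.loc["ok", "fdr"] == pytest.approx(res.loc["ok", "p_value"])

    def test_pairwise_complete_n(self):
        x = _series([1.0, 2.0, 3.0, 4.0, 5.0])
        ys = pd.DataFrame({"y": [1.0, np.nan, 2.0, 5.0, 4.0]}, index=x.index)
        res = spearman_screen(x, ys)
        assert res.loc[0, "n_pairs"] == 4


class TestMannWhitney:
    def test_worked_example_u6_p_point1(self):
        res = mannwhitney_one_sided([3, 4, 5], [1, 2], "greater")
        assert res.statistic == 6.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_groups_have_p_at_least_half(self):
        res = mannwhitney_one_sided([1, 2, 3], [1, 2, 3], "greater")
        assert res.p_value >= 0.5

    def test_anti_ordered_singletons_give_p_one(self):
        res = mannwhitney_one_sided([1], [2], "greater")
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("na,nb", [(1, 1), (2, 2), (3, 2), (4, 3), (2, 6)])
    @pytest.mark.parametrize("alternative", ["greater", "less"])
    def test_exact_branch_matches_enumeration(self, rng, na, nb, alternative):
        for _ in range(5):
            vals = rng.choice(1000, size=na + nb, replace=False).astype(float)
            a, b = vals[:na], vals[na:]
            res = mannwhitney_one_sided(a, b, alternative)
            want = mw_enumerate_p(a, b, alternative)
            assert res.p_value == pytest.approx(want, abs=1e-12)

    def test_exact_type_I_error_at_most_nominal_under_null(self, rng):
        # exhaustive: over all splits, P(p <= alpha) <= alpha
        vals = rng.choice(100, size=8, replace=False).astype(float)
        import itertools

        for alpha in (0.05, 0.1, 0.25):
            rejections = 0
            combos = list(itertools.combinations(range(8), 4))
            for comb in combos:
                a = vals[list(comb)]
                b = vals[[i for i in range(8) if i not in comb]]
                if mannwhitney_one_sided(a, b, "greater").p_value <= alpha:
                    rejections += 1
            assert rejections / len(combos) <= alpha + 1e-12

    def test_tied_data_uses_corrected_normal_approximation(self):
        res = mannwhitney_one_sided([1, 1, 2, 3], [1, 2, 2, 0], "greater")
        assert res.method == "asymptotic"
        assert 0 < res.p_value <= 1

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            mannwhitney_one_sided([], [1.0], "greater")


class TestKruskalWallis:
    def test_identical_groups_give_h0_p1(self):
        res = kruskal_wallis([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_h_on_known_ranks(self):
        # groups [1,2],[3,4],[5,6]: H = 12/(6*7) * 2*((1.5-3.5)^2 + 0 + (5.5-3.5)^2)
        res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == pytest.approx(32 / 7)

    def test_h_is_non_negative(self, rng):
        groups = [rng.normal(size=5) for _ in range(4)]
        assert kruskal_wallis(groups).statistic >= 0

    def test_two_groups_redirects_to_mannwhitney(self):
        with pytest.raises(ValueError, match="[Mm]ann"):
            kruskal_wallis([[1, 2], [3, 4]])


def _cohort(times, events, prefix="S"):
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return pd.DataFrame({"os_time": times, "os_event": events}, index=idx)


class TestKmLogrank:
    def test_km_without_censoring_equals_empirical_survival(self):
        times = [3.0, 1.0, 4.0, 2.0, 5.0, 6.0, 7.0, 8.0]
        cohort = _cohort(times, [1] * 8)
        groups = pd.Series(
            ["a"] * 4 + ["b"] * 4, index=cohort.index, dtype=object
        )
        comp = km_logrank(cohort, groups)
        emp = km_no_censoring(sorted(times[:4]))
        curve = comp.curves["a"].set_index("time")["survival"]
        for t, s in emp.items():
            assert curve[t] == pytest.approx(s)
        np.testing.assert_allclose(
            comp.curves["a"]["survival"], [1.0, 0.75, 0.5, 0.25, 0.0]
        )

    def test_curves_start_at_one_and_decrease(self, rng):
        cohort = _cohort(
            list(rng.exponential(10, size=20)), list(rng.integers(0, 2, size=20))
        )
        cohort.iloc[0, 1] = 1  # ensure an event
        groups = pd.Series(["a", "b"] * 10, index=cohort.index)
        comp = km_logrank(cohort, groups)
        for curve in comp.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] == 1.0
            assert (np.diff(surv) <= 1e-12).all()
            at_risk = curve["at_risk"].to_numpy()
            assert (np.diff(at_risk) <= 0).all()

    def test_identical_groups_give_zero_statistic_p_one(self):
        cohort = _cohort([1, 2, 3, 4, 1, 2, 3, 4], [1, 1, 0, 1, 1, 1, 0, 1])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=cohort.index)
        comp = km_logrank(cohort, groups)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_six_subject_case_matches_hand_tables(self):
        # A: events at 1, 3; censored at 5.  B: events at 2, 4, 6.
        cohort = _cohort([1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 1, 1])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cohort.index)
        in_a = [True] * 3 + [False] * 3
        ome, var, chi2 = logrank_hand(cohort["os_time"], cohort["os_event"], in_a)
        assert ome == pytest.approx(2 - (0.5 + 0.4 + 0.5 + 1 / 3))
        assert var == pytest.approx(0.25 + 0.24 + 0.25 + 2 / 9)
        comp = km_logrank(cohort, groups)
        assert comp.statistic == pytest.approx(chi2, rel=1e-10)

    def test_stratified_single_stratum_equals_unstratified(self, rng):
        times = list(rng.exponential(10, size=30))
        events = list(rng.integers(0, 2, size=30))
        cohort = _cohort(times, events)
        groups = pd.Series(["a", "b"] * 15, index=cohort.index)
        strata = pd.Series(["only"] * 30, index=cohort.index)
        plain = km_logrank(cohort, groups)
        strat = km_logrank(cohort, groups, strata=strata)
        assert strat.statistic == pytest.approx(plain.statistic, rel=1e-8)

    def test_zero_event_group_warns_but_computes(self):
        cohort = _cohort([1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 0, 0])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=cohort.index)
        with pytest.warns(UserWarning, match="zero events"):
            comp = km_logrank(cohort, groups)
        assert 0 < comp.p_value <= 1

    def test_missing_endpoint_column_is_error(self):
        cohort = _cohort([1, 2, 3, 4], [1, 1, 1, 1])
        groups = pd.Series(["a", "a", "b", "b"], index=cohort.index)
        with pytest.raises(ValueError, match="dfs_time"):
            km_logrank(cohort, groups, endpoint="dfs")


class TestBhProperties:
    @given(
        st.lists(st.floats(1e-8, 1.0, allow_nan=False), min_size=2, max_size=12)
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_bh_is_permutation_stable_and_bounded(self, pvals):
        base = bh_stepup(pvals)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(pvals)))
        permuted = bh_stepup([pvals[i] for i in perm])
        for pos, orig in enumerate(perm):
            assert permuted[pos] == pytest.approx(base[orig], rel=1e-12)
        for raw, adj in zip(pvals, base):
            assert raw - 1e-12 <= adj <= 1.0 + 1e-12

    def test_statsmodels_bh_matches_oracle_on_hand_vector(self):
        from statsmodels.stats.multitest import multipletests

        pv = [0.01, 0.02, 0.03]
        np.testing.assert_allclose(
            multipletests(pv, method="fdr_bh")[1], [0.03, 0.03, 0.03]
        )
        np.testing.assert_allclose(bh_stepup(pv), [0.03, 0.03, 0.03])
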