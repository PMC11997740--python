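"""Group comparisons, predictor selection and summary statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from savanna_carbon.stats import (
    anova_tukey,
    bartlett_variance_test,
    below_above_ratio,
    games_howell,
    pca_overview,
    percent_change,
    spearman_filter,
)
from savanna_carbon.woody import CarbonCompartments


class TestSpearmanFilter:
    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        kept, report = spearman_filter(df)
        assert len(kept) == 2 and "c" in kept
        assert report.iloc[0]["abs_rho"] == pytest.approx(1.0)

    def test_independent_noise_all_retained(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 5)), columns=list("abcde"))
        kept, report = spearman_filter(df)
        assert kept == list("abcde") and report.empty

    def test_result_satisfies_exhaustive_pairwise_check(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=120)
        df = pd.DataFrame({
            "a": base, "b": base + 0.1 * rng.normal(size=120),
            "c": base + 0.3 * rng.normal(size=120), "d": rng.normal(size=120),
            "e": -base + 0.2 * rng.normal(size=120),
        })
        kept, _ = spearman_filter(df, threshold=0.75)
        for c1, c2 in itertools.combinations(kept, 2):
            rho = sps.spearmanr(df[c1], df[c2]).statistic
            assert abs(rho) < 0.75

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            spearman_filter(df)


class TestPca:
    def test_perfectly_correlated_pair_loads_on_single_component(self):
        x = np.arange(50.0)
        out = pca_overview(pd.DataFrame({"a": x, "b": 2 * x + 1}))
        assert out["variance_shares"][0] == pytest.approx(1.0)

    def test_shares_equal_normalised_eigenvalues_of_correlation_matrix(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(200, 6)), columns=list("abcdef"))
        out = pca_overview(df)
        w = np.linalg.eigvalsh(np.corrcoef(
            ((df - df.mean()) / df.std(ddof=1)).to_numpy(), rowvar=False
        ))[::-1]
        assert np.allclose(out["variance_shares"], w / w.sum())
        assert out["variance_shares"].sum() == pytest.approx(1.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            pca_overview(pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}))


class TestBartlett:
    def test_matches_textbook_formula_on_hand_computed_triple(self):
        groups = [np.array([1.0, 2.0, 3.0, 4.0]),
                  np.array([2.0, 4.0, 6.0, 8.0]),
                  np.array([1.0, 1.5, 2.0, 2.5])]
        stat, p = bartlett_variance_test(groups)
        # brute-force Bartlett statistic
        k = 3
        ns = np.array([len(g) for g in groups])
        vs = np.array([g.var(ddof=1) for g in groups])
        n_tot = ns.sum()
        sp2 = ((ns - 1) * vs).sum() / (n_tot - k)
        num = (n_tot - k) * np.log(sp2) - ((ns - 1) * np.log(vs)).sum()
        den = 1 + (np.sum(1 / (ns - 1)) - 1 / (n_tot - k)) / (3 * (k - 1))
        assert stat == pytest.approx(num / den, rel=1e-10)
        assert p == pytest.approx(sps.chi2.sf(num / den, k - 1), rel=1e-10)

    def test_identical_groups_give_zero_statistic(self):
        g = np.array([1.0, 2.0, 3.0])
        stat, p = bartlett_variance_test([g, g.copy()])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 20) for _ in range(3)]
            _, p = bartlett_variance_test(groups)
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            bartlett_variance_test([np.ones(5), np.arange(5.0)])


class TestGamesHowell:
    def test_identical_groups_no_difference(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = games_howell({"a": g, "b": g.copy()})[0]
        assert res.mean_diff == 0.0
        assert res.p_adjusted == pytest.approx(1.0)

    def test_two_groups_reduce_to_welch_t(self):
        """At k=2 the studentized-range p equals the two-sided Welch t p."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 2.5, 7)
        res = games_howell({"a": a, "b": b})[0]
        t = sps.ttest_ind(a, b, equal_var=False)
        assert res.q_statistic == pytest.approx(abs(t.statistic) * np.sqrt(2), rel=1e-9)
        assert res.p_adjusted == pytest.approx(t.pvalue, rel=1e-4)
        assert res.df == pytest.approx(t.df, rel=1e-9)

    def test_symmetric_in_pair_order_up_to_sign(self):
        rng = np.random.default_rng(8)
        g = {"a": rng.normal(size=10), "b": rng.normal(size=8), "c": rng.normal(size=12)}
        res = {(r.group_1, r.group_2): r for r in games_howell(g)}
        rev = {(r.group_1, r.group_2): r for r in games_howell(dict(reversed(list(g.items()))))}
        r1, r2 = res[("a", "b")], rev[("b", "a")]
        assert r1.mean_diff == pytest.approx(-r2.mean_diff)
        assert r1.p_adjusted == pytest.approx(r2.p_adjusted)

    def test_matches_pingouin_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        data = pd.DataFrame({
            "y": np.concatenate([rng.normal(m, s, n) for m, s, n in
                                 [(0, 1, 10), (1, 2, 6), (0.5, 0.5, 8)]]),
            "g": ["a"] * 10 + ["b"] * 6 + ["c"] * 8,
        })
        ours = {frozenset((r.group_1, r.group_2)): r for r in games_howell(
            {k: v["y"].to_numpy() for k, v in data.groupby("g")}
        )}
        ref = pg.pairwise_gameshowell(data=data, dv="y", between="g")
        for _, row in ref.iterrows():
            r = ours[frozenset((row["A"], row["B"]))]
            assert r.df == pytest.approx(row["df"], rel=1e-6)
            assert r.p_adjusted == pytest.approx(row["pval"], abs=1e-6)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            games_howell({"a": np.array([1.0]), "b": np.arange(3.0)})


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=15)
        out = anova_tukey({"a": base, "b": base + 1e-9, "c": base - 1e-9})
        letters = set(out["letters"].values())
        assert len(letters) == 1

    def test_extreme_shift_separates_letters(self):
        rng = np.random.default_rng(11)
        out = anova_tukey({
            "a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
            "c": rng.normal(10, 1, 15),
        })
        assert out["letters"]["c"] != out["letters"]["a"]
        assert out["p_value"] < 1e-6

    def test_f_statistic_matches_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(12)
        groups = {k: rng.normal(i, 1, 10 + i) for i, k in enumerate("abc")}
        out = anova_tukey(groups)
        allv = np.concatenate(list(groups.values()))
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
        k, n = len(groups), len(allv)
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert out["f_statistic"] == pytest.approx(f, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"a": np.arange(5.0)})


class TestSummaries:
    def test_percent_change_worked_values(self):
        assert percent_change(9.0, 6.3) == pytest.approx(-30.0)
        assert percent_change(10.0, 20.0) == pytest.approx(100.0)
        assert percent_change(5.0, 5.0) == 0.0

    def test_percent_change_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 5.0)

    def test_below_above_ratio(self):
        c = CarbonCompartments(
            plot_id="p", tree_agc=6.0, shrub_agc=4.0, tree_bgc=8.0, shrub_bgc=2.0,
            topsoil_soc=12.0, subsoil_soc=18.0,
        )
        assert below_above_ratio(c) == pytest.approx((10 + 30) / 10)
        doubled = CarbonCompartments(
            plot_id="p", tree_agc=12.0, shrub_agc=8.0, tree_bgc=16.0, shrub_bgc=4.0,
            topsoil_soc=24.0, subsoil_soc=36.0,
        )
        assert below_above_ratio(doubled) == pytest.approx(below_above_ratio(c))

    def test_ratio_undefined_for_zero_agc(self):
        c = CarbonCompartments(plot_id="p", topsoil_soc=10.0)
        assert np.isnan(below_above_ratio(c))
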