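"""Group tests, multiplicity control, Mantel, macro-nutrient summary."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

import ampliem as am
from oracles import studentized_range_sf


class TestChiSquareCramersV:
    def test_proportional_table_is_null(self):
        res = am.chi_square_cramers_v([[10, 20], [20, 40]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["cramers_v"] == pytest.approx(0.0, abs=1e-9)

    def test_perfect_association_v_one(self):
        res = am.chi_square_cramers_v([[10, 0], [0, 10]])
        assert res["cramers_v"] == pytest.approx(1.0)

    def test_zero_marginal_fails(self):
        with pytest.raises(ValueError):
            am.chi_square_cramers_v([[0, 0], [1, 2]])


class TestAnovaTukey:
    def test_equal_group_means_give_zero_f_and_unit_p(self):
        y = [1, 2, 3] * 3
        g = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = am.anova_tukey(y, g)
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert (res.pairwise["p_adj"] > 0.999).all()
        assert (res.pairwise["estimate"] == 0).all()

    def test_matches_statsmodels_tukeyhsd(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(m, 1, 12) for m in (0, 0.8, 1.5)])
        g = np.repeat(list("abc"), 12)
        res = am.anova_tukey(y, g)
        sm = pairwise_tukeyhsd(y, g)
        assert np.allclose(
            sorted(res.pairwise["p_adj"]), sorted(sm.pvalues), atol=1e-8
        )
        assert np.allclose(
            sorted(np.abs(res.pairwise["estimate"])),
            sorted(np.abs(sm.meandiffs)),
            atol=1e-12,
        )

    def test_adjusted_p_matches_quadrature_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(6):
            sizes = rng.integers(4, 10, size=3)
            y = np.concatenate([rng.normal(m, 1, n) for m, n in zip((0, 1, 2), sizes)])
            g = np.repeat(list("abc"), sizes)
            res = am.anova_tukey(y, g)
            k, df = 3, res.df_resid
            for contrast, row in res.pairwise.iterrows():
                a, b = contrast.split(" vs. ")
                na, nb = sizes[ord(a) - 97], sizes[ord(b) - 97]
                q = abs(row["estimate"]) / np.sqrt(
                    res.mse / 2 * (1 / na + 1 / nb)
                )
                assert row["p_adj"] == pytest.approx(
                    studentized_range_sf(round(q, 9), k, df), abs=1e-6
                )

    def test_covariate_absorbs_spurious_group_effect(self):
        # group differences in y driven entirely by the covariate
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(m, 1, 20) for m in (0, 2, 4)])
        y = 3 * x + rng.normal(0, 0.5, 60)
        g = np.repeat(list("abc"), 20)
        raw = am.anova_tukey(y, g)
        adj = am.anova_tukey(y, g, covariate=x)
        assert raw.p < 0.001
        assert adj.p > 0.05

    def test_degenerate_group_fails(self):
        with pytest.raises(ValueError):
            am.anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestKruskalWallis:
    def test_complete_rank_separation_closed_form(self):
        res = am.kruskal_wallis([1, 2, 3, 4, 5, 10, 11, 12, 13, 14], ["a"] * 5 + ["b"] * 5)
        assert res["H"] == pytest.approx(12 / 110 * 62.5)  # 6.8181...

    def test_constant_values_unit_p(self):
        res = am.kruskal_wallis([5.0] * 9, ["a", "b", "c"] * 3)
        assert res["H"] == 0.0 and res["p"] == 1.0

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(3)
        rej = 0
        reps = 500
        for _ in range(reps):
            y = rng.normal(size=30)
            res = am.kruskal_wallis(y, np.repeat(list("abc"), 10))
            rej += res["p"] < 0.05
        assert 0.03 <= rej / reps <= 0.075


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert am.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_arithmetic(self):
        assert am.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_equal_inputs_stay_equal(self):
        out = am.bh_fdr([0.2] * 5)
        assert np.allclose(out, 0.2)

    def test_matches_hand_step_up_and_is_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        out = am.bh_fdr(p)
        n = len(p)
        order = np.argsort(p)
        hand = np.empty(n)
        prev = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            prev = min(prev, p[i] * n / (rank + 1))
            hand[i] = prev
        assert np.allclose(out, hand)
        assert (out <= 1.0).all()


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2, 3, 5, 8]
        assert am.spearman(x, x)["rho"] == pytest.approx(1.0)
        assert am.spearman(x, [-v for v in x])["rho"] == pytest.approx(-1.0)

    def test_rank_arithmetic_example(self):
        assert am.spearman([1, 2, 3, 4], [2, 1, 4, 3])["rho"] == pytest.approx(0.6)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning):
            res = am.spearman([1, 1, 1], [1, 2, 3])
        assert np.isnan(res["rho"])


class TestMantel:
    @staticmethod
    def _random_dist(rng, n):
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return d

    def test_self_correlation_hits_lower_bound(self):
        rng = np.random.default_rng(5)
        d = self._random_dist(rng, 12)
        res = am.mantel(d, d, permutations=99, seed=0)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 100)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        d = self._random_dist(rng, 10)
        res = am.mantel(d, 2.5 * d + 0.3 * (1 - np.eye(10)), permutations=49, seed=0)
        assert res["r"] == pytest.approx(1.0)

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        ps = []
        for i in range(200):
            d1 = self._random_dist(rng, 10)
            d2 = self._random_dist(rng, 10)
            ps.append(am.mantel(d1, d2, permutations=99, seed=i)["p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestMacroSummary:
    def test_pure_fat(self):
        out = am.macro_summary(
            pd.DataFrame({"fat_g": [100.0], "protein_g": [0.0], "carbohydrate_g": [0.0]})
        )
        assert out["kcal_total"].iloc[0] == pytest.approx(900.0)
        assert out["pct_fat"].iloc[0] == pytest.approx(100.0)

    def test_mixed_meal_arithmetic(self):
        out = am.macro_summary(
            pd.DataFrame({"fat_g": [50.0], "protein_g": [75.0], "carbohydrate_g": [250.0]})
        )
        assert out["kcal_total"].iloc[0] == pytest.approx(1750.0)
        assert out["pct_fat"].iloc[0] == pytest.approx(450 / 1750 * 100)
        assert out["pct_protein"].iloc[0] == pytest.approx(300 / 1750 * 100)
        assert out["pct_carbohydrate"].iloc[0] == pytest.approx(1000 / 1750 * 100)
        assert (
            out[["pct_fat", "pct_protein", "pct_carbohydrate"]].sum(axis=1).iloc[0]
            == pytest.approx(100.0)
        )
        assert out["delta_fat"].iloc[0] == pytest.approx(450 / 1750 * 100 - 30)

    def test_zero_energy_missing_with_warning(self):
        with pytest.warns(UserWarning):
            out = am.macro_summary(
                pd.DataFrame({"fat_g": [0.0], "protein_g": [0.0], "carbohydrate_g": [0.0]})
            )
        assert np.isnan(out["pct_fat"].iloc[0])


def test_differential_abundance_uses_one_bh_family():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(
        rng.poisson(20, size=(15, 16)),
        index=[f"t{i}" for i in range(15)],
        columns=[f"s{i}" for i in range(16)],
    )
    counts.iloc[0, 8:] += 200  # one strongly shifted taxon
    groups = pd.Series(["a"] * 8 + ["b"] * 8, index=counts.columns)
    out = am.differential_abundance(counts, groups)
    assert out.loc["t0", "significant"]
    assert np.allclose(out["p_adj"], am.bh_fdr(out["p"].to_numpy()))
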