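"""Statistical tests checked against scipy/statsmodels and brute force."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from musicnet import groupstats as gs


class TestTTests:
    def test_one_sample_matches_scipy(self, rng):
        x = rng.standard_normal(15) + 0.4
        res = gs.one_sample_t(x, popmean=0.1)
        ref = stats.ttest_1samp(x, 0.1)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.effect_size == pytest.approx(
            (x.mean() - 0.1) / x.std(ddof=1), abs=1e-12
        )

    def test_two_sample_matches_scipy(self, rng):
        a = rng.standard_normal(12) + 0.5
        b = rng.standard_normal(9)
        res = gs.two_sample_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.df == 19

    def test_paired_matches_scipy(self, rng):
        a = rng.standard_normal(10)
        b = a + 0.3 + 0.1 * rng.standard_normal(10)
        res = gs.paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_degenerate_inputs(self):
        res = gs.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0
        with pytest.raises(ValueError):
            gs.two_sample_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            gs.paired_t([1.0, 2.0], [1.0, 2.0, 3.0])


class TestAnova:
    def _unbalanced_data(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for cond in ("c1", "c2"):
            for state in ("s0", "s1"):
                n = int(rng.integers(5, 12))
                mu = {"c1": 0.0, "c2": 0.4}[cond] + {"s0": 0.0, "s1": 1.0}[state]
                if cond == "c2" and state == "s1":
                    mu += 0.5  # interaction
                for v in mu + rng.standard_normal(n):
                    rows.append({"y": v, "cond": cond, "state": state})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_type_ii_matches_statsmodels(self, seed):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = self._unbalanced_data(seed)
        res = gs.two_way_anova(df["y"], df["cond"], df["state"])
        fit = ols("y ~ C(cond) * C(state)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=2)
        for name, row in (
            ("condition", "C(cond)"),
            ("state", "C(state)"),
            ("interaction", "C(cond):C(state)"),
        ):
            assert res[name].statistic == pytest.approx(ref.loc[row, "F"], abs=1e-10)
            assert res[name].p_value == pytest.approx(ref.loc[row, "PR(>F)"], abs=1e-10)
        assert res["condition"].df == (1, len(df) - 4)

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            gs.two_way_anova(
                [1.0, 2.0, 3.0, 4.0],
                ["c1", "c1", "c2", "c2"],
                ["s0", "s0", "s1", "s1"],
            )


class TestTukeyKramer:
    def test_balanced_case_matches_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        y = np.concatenate(
            [rng.standard_normal(8) + mu for mu in (0.0, 0.8, 2.0)]
        )
        g = np.repeat(["a", "b", "c"], 8)
        ref = pairwise_tukeyhsd(y, g)
        means = [y[g == lv].mean() for lv in ("a", "b", "c")]
        mse = sum(((y[g == lv] - y[g == lv].mean()) ** 2).sum() for lv in "abc") / 21
        tk = gs.tukey_kramer(means, [8, 8, 8], mse, 21)
        assert np.allclose(tk["p"].to_numpy(), ref.pvalues, atol=1e-8)
        assert np.allclose(-tk["mean_diff"].to_numpy(), ref.meandiffs, atol=1e-10)

    def test_unequal_ns_use_kramer_se(self):
        tk = gs.tukey_kramer([0.0, 1.0], [4, 9], mse=2.0, df_error=11)
        se = np.sqrt(2.0 / 2.0 * (1 / 4 + 1 / 9))
        assert tk.loc[0, "q"] == pytest.approx(1.0 / se, abs=1e-12)
        assert 0.0 <= tk.loc[0, "p"] <= 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            gs.tukey_kramer([0.0], [5], 1.0, 4)
        with pytest.raises(ValueError):
            gs.tukey_kramer([0.0, 1.0], [5, 1], 1.0, 4)
        with pytest.raises(ValueError):
            gs.tukey_kramer([0.0, 1.0], [5, 5], 0.0, 8)


class TestMannWhitney:
    def test_exact_matches_scipy(self, rng):
        a = rng.standard_normal(6)
        b = rng.standard_normal(8) + 1.0
        res = gs.mann_whitney_u(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.test_name == "mann_whitney_u_exact"
        u_a = ref.statistic
        assert res.statistic == min(u_a, 48 - u_a)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_distribution_matches_brute_force_enumeration(self, rng):
        # enumerate all C(n1+n2, n1) rank splits; the U_a histogram must
        # equal the DP recursion's count table
        from collections import Counter

        for n1, n2 in ((3, 4), (4, 4), (2, 6)):
            counts = gs._u_count_distribution(n1, n2)
            brute = Counter()
            for idx in itertools.combinations(range(n1 + n2), n1):
                ra = sum(r + 1 for r in idx)
                brute[int(ra - n1 * (n1 + 1) / 2)] += 1
            for u_val in range(n1 * n2 + 1):
                assert counts[u_val] == brute.get(u_val, 0)
        # and the two-sided p doubles the lower tail of that distribution
        a = rng.standard_normal(3)
        b = rng.standard_normal(4)
        res = gs.mann_whitney_u(a, b)
        counts = gs._u_count_distribution(3, 4)
        p_brute = min(2.0 * counts[: int(res.statistic) + 1].sum() / counts.sum(), 1.0)
        assert res.p_value == pytest.approx(p_brute, abs=1e-15)

    def test_ties_fall_back_to_approx(self):
        res = gs.mann_whitney_u([1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0, 6.0])
        assert res.test_name == "mann_whitney_u_approx"
        ref = stats.mannwhitneyu(
            [1.0, 2.0, 2.0, 3.0], [2.0, 4.0, 5.0, 6.0],
            alternative="two-sided", method="asymptotic",
        )
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_rank_biserial_bounds(self, rng):
        a = rng.standard_normal(5) + 10.0  # complete separation
        b = rng.standard_normal(5)
        res = gs.mann_whitney_u(a, b)
        assert res.statistic == 0.0
        assert res.effect_size == 1.0


class TestFdrAndDensity:
    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(40) ** 2
        qv, surv = gs.bh_fdr(p, q=0.05)
        rej, q_ref, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(qv, q_ref, atol=1e-12)
        assert np.array_equal(surv, rej)

    def test_bh_edge_cases(self):
        qv, surv = gs.bh_fdr([])
        assert qv.size == 0 and surv.size == 0
        qv, surv = gs.bh_fdr([0.001])
        assert surv[0]
        with pytest.raises(ValueError):
            gs.bh_fdr([0.5, 1.5])

    def test_edge_density_hand(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = -0.2
        assert gs.edge_density(W) == pytest.approx(2 / 6)
        assert gs.edge_density(np.zeros((3, 3))) == 0.0


class TestNodalWorkflow:
    def test_screen_and_group_comparison_recover_planted_nodes(self, rng):
        n_sub, n_nodes = 20, 15
        vals = rng.standard_normal((n_sub, n_nodes)) * 0.5
        vals[:, :10] += 3.0  # ten real nodes
        screen = gs.nodal_one_sample_screen(vals)
        survivors = screen.loc[screen["survives"], "node"].to_numpy()
        assert set(range(10)) <= set(survivors)
        # group difference planted at node 0 only
        a = vals[:10].copy()
        a[:, 0] += 2.0
        comp = gs.nodal_group_comparison(a, vals[10:], survivors)
        sig = set(comp.loc[comp["survives"], "node"])
        assert 0 in sig

    def test_empty_survivor_list(self, rng):
        vals = rng.standard_normal((8, 5))
        comp = gs.nodal_group_comparison(vals[:4], vals[4:], [])
        assert comp.empty
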