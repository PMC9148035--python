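"""Cross-cluster tests against hand, closed-form and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats

from nutripatterns import (
    anova_tukey,
    chi_squared_mc,
    kruskal_mw_mc,
    levene_test,
    welch_games_howell,
)
from nutripatterns.group_comparison import (
    assign_letters,
    compare_across_clusters,
    games_howell_df,
)


# ---------------------------------------------------------------- oracles
def levene_hand_oracle(groups):
    """One-way ANOVA on absolute deviations from group means, via raw sums."""
    devs = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
    pooled = np.concatenate(devs)
    grand = pooled.mean()
    k = len(devs)
    n = len(pooled)
    ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
    return (ssb / (k - 1)) / (ssw / (n - k))


def kw_exact_p(x, y):
    """Exact permutation p of the KW statistic for two small groups."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = stats.kruskal(x, y).statistic
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        a = pooled[list(comb)]
        b = pooled[[i for i in range(len(pooled)) if i not in comb]]
        h = stats.kruskal(a, b).statistic
        total += 1
        if h >= obs - 1e-12:
            count += 1
    return count / total


def chi2_exact_p(table):
    """Exact conditional p of Pearson chi2 over all margin-fixed tables."""
    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = table.sum()
    expected = np.outer(rows, cols) / N

    def chi2(t):
        return ((t - expected) ** 2 / expected).sum()

    obs = chi2(table)
    log_const = (
        sum(math.lgamma(r + 1) for r in rows)
        + sum(math.lgamma(c + 1) for c in cols)
        - math.lgamma(N + 1)
    )
    p = 0.0
    r, c = table.shape
    assert (r, c) == (2, 3)

    def prob(t):
        return math.exp(log_const - sum(math.lgamma(v + 1) for v in t.ravel()))

    for a in range(min(rows[0], cols[0]) + 1):
        for b in range(min(rows[0] - a, cols[1]) + 1):
            d = rows[0] - a - b
            if d > cols[2]:
                continue
            t = np.array([[a, b, d], [cols[0] - a, cols[1] - b, cols[2] - d]])
            if (t < 0).any():
                continue
            if chi2(t) >= obs - 1e-12:
                p += prob(t)
    return p


# ------------------------------------------------------------------ Levene
class TestLevene:
    def test_identical_groups_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = levene_test([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_detects_tenfold_sd(self):
        rng = np.random.default_rng(0)
        res = levene_test([rng.normal(0, 1, 50), rng.normal(0, 10, 50)])
        assert res.p_value < 0.01

    def test_hand_oracle_two_groups_of_three(self):
        g1 = [1.0, 4.0, 7.0]
        g2 = [2.0, 2.5, 9.0]
        res = levene_test([g1, g2])
        assert res.statistic == pytest.approx(levene_hand_oracle([g1, g2]), rel=1e-12)


# ------------------------------------------------------------- ANOVA/Tukey
class TestAnovaTukey:
    def test_clearly_separated_groups(self):
        rng = np.random.default_rng(1)
        g1 = rng.normal(0, 1e-3, 10)
        g2 = rng.normal(1, 1e-3, 10)
        res = anova_tukey([g1, g2], names=["a", "b"])
        assert res.p_value < 1e-10
        assert res.letters["a"] != res.letters["b"]

    def test_two_group_tukey_equals_t_test(self):
        rng = np.random.default_rng(2)
        g1 = rng.normal(0, 1, 15)
        g2 = rng.normal(0.5, 1, 12)
        res = anova_tukey([g1, g2])
        t_p = stats.ttest_ind(g1, g2).pvalue
        assert res.pairwise.iloc[0, 1] == pytest.approx(t_p, rel=1e-6)

    def test_pairwise_symmetric(self):
        rng = np.random.default_rng(3)
        gs = [rng.normal(m, 1, 20) for m in (0, 0.5, 2.0)]
        res = anova_tukey(gs)
        pd.testing.assert_frame_equal(res.pairwise, res.pairwise.T)
        assert ((res.pairwise.to_numpy() >= 0) & (res.pairwise.to_numpy() <= 1)).all()


# ----------------------------------------------------- Welch / Games-Howell
class TestWelchGamesHowell:
    def test_homoscedastic_close_to_classic_f(self):
        rng = np.random.default_rng(4)
        gs = [rng.normal(m, 1, 100) for m in (0.0, 0.3, 0.6)]
        res = welch_games_howell(gs)
        F = stats.f_oneway(*gs).statistic
        assert res.statistic == pytest.approx(F, rel=0.05)

    def test_identical_groups_boundary(self):
        g = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = welch_games_howell([g, g.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.pairwise.iloc[0, 1] == pytest.approx(1.0)

    def test_pairwise_df_matches_hand_satterthwaite(self):
        gs = [np.array([1.0, 2.0, 6.0]),
              np.array([2.0, 9.0, 11.0, 20.0]),
              np.array([1.0, 1.5, 2.0, 2.5, 3.0])]
        for (i, j) in [(0, 1), (0, 2), (1, 2)]:
            v1, n1 = np.var(gs[i], ddof=1), len(gs[i])
            v2, n2 = np.var(gs[j], ddof=1), len(gs[j])
            hand = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            assert games_howell_df(v1, n1, v2, n2) == pytest.approx(hand, rel=1e-12)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(5)
        gs = [rng.normal(0, 1, 20), rng.normal(1, 3, 25), rng.normal(2, 0.5, 15)]
        res = welch_games_howell(gs, names=["a", "b", "c"])
        df = pd.DataFrame({
            "y": np.concatenate(gs),
            "g": np.repeat(["a", "b", "c"], [20, 25, 15]),
        })
        wa = pg.welch_anova(data=df, dv="y", between="g")
        assert res.statistic == pytest.approx(float(wa["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(wa["p_unc"].iloc[0]), rel=1e-6)
        gh = pg.pairwise_gameshowell(data=df, dv="y", between="g")
        for _, row in gh.iterrows():
            assert res.pairwise.loc[row["A"], row["B"]] == pytest.approx(
                float(row["pval"]), abs=1e-6)

    def test_tukey_games_howell_coincide_for_equal_variance_pairs(self):
        rng = np.random.default_rng(6)
        g1 = rng.normal(0, 1, 20)
        g2 = g1 + 0.8  # identical variance by construction
        tk = anova_tukey([g1, g2])
        gh = welch_games_howell([g1, g2])
        assert tk.pairwise.iloc[0, 1] == pytest.approx(gh.pairwise.iloc[0, 1], abs=1e-6)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_games_howell([np.ones(5), np.array([1.0, 2.0, 3.0])])


# -------------------------------------------------- Monte-Carlo machinery
class TestKruskalMWMonteCarlo:
    def test_matches_exact_enumeration(self):
        x = np.array([1.0, 5.0, 9.0])
        y = np.array([2.0, 3.0, 12.0])
        exact = kw_exact_p(x, y)
        res = kruskal_mw_mc([x, y], n_mc=10_000, seed=0, pairwise=False)
        assert abs(res.p_value - exact) < 0.02

    def test_large_shift_hits_lower_bound(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 40)
        y = rng.normal(30, 1, 40)
        res = kruskal_mw_mc([x, y], n_mc=2000, seed=1, pairwise=False)
        assert res.p_value == pytest.approx(1 / 2001, abs=2e-3)

    def test_reproducible_and_bounded(self):
        rng = np.random.default_rng(8)
        gs = [rng.normal(0, 1, 12) for _ in range(3)]
        r1 = kruskal_mw_mc(gs, n_mc=500, seed=3)
        r2 = kruskal_mw_mc(gs, n_mc=500, seed=3)
        assert r1.p_value == r2.p_value
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)
        assert 1 / 501 <= r1.p_value <= 1.0
        assert (r1.pairwise.to_numpy() >= 1 / 501 - 1e-12).all()

    def test_all_identical_values_p_one(self):
        res = kruskal_mw_mc([np.ones(5), np.ones(6)], n_mc=100, seed=0)
        assert res.p_value == 1.0

    def test_pairwise_consistent_with_statistic(self):
        rng = np.random.default_rng(9)
        gs = [rng.normal(0, 1, 15), rng.normal(0, 1, 15), rng.normal(4, 1, 15)]
        res = kruskal_mw_mc(gs, n_mc=2000, seed=4)
        assert res.pairwise.iloc[0, 1] > 0.05      # null pair
        assert res.pairwise.iloc[0, 2] < 0.01      # shifted pair
        assert res.letters[1] == res.letters[2] != res.letters[3]


class TestChiSquaredMonteCarlo:
    def test_identical_row_distributions_null(self):
        res = chi_squared_mc([[10, 20, 30], [10, 20, 30]], n_mc=500, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_perfect_association_lower_bound(self):
        res = chi_squared_mc([[10, 0], [0, 10]], n_mc=2000, seed=1)
        assert res.p_value <= 3 / 2001

    def test_matches_exact_enumeration_2x3(self):
        table = [[3, 1, 4], [1, 5, 2]]
        exact = chi2_exact_p(table)
        res = chi_squared_mc(table, n_mc=10_000, seed=2)
        assert abs(res.p_value - exact) < 0.02

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_mc([[0, 0], [1, 2]])
        with pytest.raises(ValueError):
            chi_squared_mc([[1, 0], [2, 0]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_mc([[1.5, 2], [3, 4]])


class TestLetters:
    def test_chain_structure(self):
        means = {"a": 3.0, "b": 2.0, "c": 1.0}
        pw = pd.DataFrame(
            [[1.0, 0.3, 0.01], [0.3, 1.0, 0.3], [0.01, 0.3, 1.0]],
            index=list("abc"), columns=list("abc"))
        letters = assign_letters(means, pw)
        assert letters["a"] != letters["c"]
        assert set(letters["b"]) == set(letters["a"] + letters["c"])

    def test_router_selects_welch_for_heteroscedastic(self):
        rng = np.random.default_rng(10)
        y = np.concatenate([rng.normal(0, 1, 60), rng.normal(1, 8, 60)])
        labels = np.repeat([1, 2], 60)
        res = compare_across_clusters(y, labels)
        assert "Welch" in res.test
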