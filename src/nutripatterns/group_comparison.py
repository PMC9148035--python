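"""Cross-cluster statistical comparisons.

Parametric (one-way ANOVA + Tukey HSD), robust (Welch ANOVA + Games-Howell)
and non-parametric (Kruskal-Wallis + pairwise Mann-Whitney) routes, plus the
chi-squared test for contingency tables. Non-parametric and chi-squared
p-values are computed by Monte-Carlo simulation (default 10,000 random
samples) with the add-one estimator p = (b + 1)/(m + 1), which is a valid
p-value regardless of distributional assumptions. Homogeneity of variance is
screened with Levene's test (mean-centered).

Pairwise results carry homogeneous-subset letters: groups sharing a letter
are not significantly different at the chosen alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_N_MC = 10_000


@dataclass
class ComparisonResult:
    """Outcome of one omnibus test with optional pairwise follow-up."""

    test: str
    statistic: float
    df: tuple | float | None
    p_value: float
    p_method: str = "analytic"             # or "monte_carlo"
    pairwise: pd.DataFrame | None = None   # symmetric group x group p-values
    letters: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{self.test}: statistic = {self.statistic:.4g}, "
                 f"p = {self.p_value:.4g} ({self.p_method})"]
        if self.pairwise is not None:
            lines.append(self.pairwise.round(4).to_string())
        if self.letters:
            lines.append("homogeneous subsets: " + ", ".join(
                f"{g}: {v}" for g, v in self.letters.items()))
        return "\n".join(lines)


def _as_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def assign_letters(means: dict, pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Compact letter display: maximal runs of mutually non-distinct groups.

    Groups are ordered by descending mean; each maximal contiguous run whose
    internal pairwise p-values all exceed ``alpha`` receives one letter.
    """
    order = sorted(means, key=lambda g: -means[g])
    n = len(order)
    intervals = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and all(
            pairwise.loc[order[a], order[j + 1]] >= alpha for a in range(i, j + 1)
        ):
            j += 1
        intervals.append((i, j))
        i = i + 1 if j == i else j  # restart inside the previous run
    # drop intervals contained in another
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv for o in intervals)]
    letters = {g: "" for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter, (lo, hi) in zip(alphabet, maximal):
        for idx in range(lo, hi + 1):
            letters[order[idx]] += letter
    return letters


def levene_test(groups) -> ComparisonResult:
    """Levene's test of variance homogeneity (deviations from group means)."""
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least two observations")
    stat, p = stats.levene(*gs, center="mean")
    k = len(gs)
    n = sum(len(g) for g in gs)
    return ComparisonResult("Levene", float(stat), (k - 1, n - k), float(p))


def anova_tukey(groups, names=None, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and subset letters."""
    gs = _as_groups(groups)
    names = list(names) if names is not None else list(range(1, len(gs) + 1))
    F, p = stats.f_oneway(*gs)
    k = len(gs)
    n = sum(len(g) for g in gs)
    hsd = stats.tukey_hsd(*gs)
    pw = pd.DataFrame(hsd.pvalue, index=names, columns=names)
    means = {nm: float(np.mean(g)) for nm, g in zip(names, gs)}
    letters = assign_letters(means, pw, alpha)
    return ComparisonResult("one-way ANOVA + Tukey HSD", float(F),
                            (k - 1, n - k), float(p), "analytic", pw, letters)


def welch_games_howell(groups, names=None, alpha: float = 0.05) -> ComparisonResult:
    """Welch's heteroscedastic ANOVA with Games-Howell pairwise tests.

    Welch F uses variance-weighted means with Satterthwaite denominator df;
    each Games-Howell pair uses its own Welch df and the studentized-range
    distribution on q = |mean difference| / SE * sqrt(2).
    """
    gs = _as_groups(groups)
    if any(len(g) < 2 for g in gs):
        raise ValueError("each group needs at least two observations")
    if any(np.var(g, ddof=1) == 0 for g in gs):
        raise ValueError("zero-variance group: Welch ANOVA undefined")
    names = list(names) if names is not None else list(range(1, len(gs) + 1))
    k = len(gs)
    ns = np.array([len(g) for g in gs], dtype=float)
    ms = np.array([np.mean(g) for g in gs])
    vs = np.array([np.var(g, ddof=1) for g in gs])

    w = ns / vs
    mw = (w * ms).sum() / w.sum()
    a = (w * (ms - mw) ** 2).sum() / (k - 1)
    tmp = (((1 - w / w.sum()) ** 2) / (ns - 1)).sum()
    b = 1 + 2 * (k - 2) / (k ** 2 - 1) * tmp
    F = a / b
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3 * tmp)
    p = float(stats.f.sf(F, df1, df2))

    pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i in range(k):
        for j in range(i + 1, k):
            se2 = vs[i] / ns[i] + vs[j] / ns[j]
            q = abs(ms[i] - ms[j]) / np.sqrt(se2) * np.sqrt(2.0)
            df_ij = se2 ** 2 / (
                (vs[i] / ns[i]) ** 2 / (ns[i] - 1) + (vs[j] / ns[j]) ** 2 / (ns[j] - 1)
            )
            pij = float(stats.studentized_range.sf(q, k, df_ij))
            pw.iloc[i, j] = pw.iloc[j, i] = pij
    means = {nm: float(m) for nm, m in zip(names, ms)}
    letters = assign_letters(means, pw, alpha)
    return ComparisonResult("Welch ANOVA + Games-Howell", float(F),
                            (df1, float(df2)), p, "analytic", pw, letters)


def games_howell_df(v1: float, n1: int, v2: float, n2: int) -> float:
    """Welch-Satterthwaite df of one Games-Howell pair (exposed for checks)."""
    se2 = v1 / n1 + v2 / n2
    return se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))


def _kw_statistic_from_ranks(rank_matrix: np.ndarray, sizes: np.ndarray,
                             tie_correction: float) -> np.ndarray:
    """Kruskal-Wallis H for each row of a (reps, n) matrix of midranks."""
    n = rank_matrix.shape[-1]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    h = np.zeros(rank_matrix.shape[0])
    for g in range(len(sizes)):
        rs = rank_matrix[:, bounds[g]:bounds[g + 1]].sum(axis=1)
        h += rs ** 2 / sizes[g]
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_correction


def _mc_pvalue(perm_stats: np.ndarray, observed: float) -> float:
    b = int(np.sum(perm_stats >= observed - 1e-12))
    return (b + 1) / (len(perm_stats) + 1)


def kruskal_mw_mc(groups, n_mc: int = DEFAULT_N_MC, seed: int = 0,
                  names=None, alpha: float = 0.05,
                  bonferroni: bool = False, pairwise: bool = True) -> ComparisonResult:
    """Kruskal-Wallis with Monte-Carlo p-value and pairwise Mann-Whitney.

    The omnibus H (midrank ties) and each pairwise MW statistic are referred
    to their permutation distributions (``n_mc`` label permutations); all
    p-values use the add-one estimator (b + 1)/(m + 1). If every pooled
    value is identical, p = 1 by convention. ``bonferroni`` optionally
    adjusts the pairwise p-values.
    """
    gs = _as_groups(groups)
    names = list(names) if names is not None else list(range(1, len(gs) + 1))
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(gs)
    sizes = np.array([len(g) for g in gs])
    n = len(pooled)

    if np.all(pooled == pooled[0]):
        k = len(gs)
        pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        return ComparisonResult("Kruskal-Wallis (MC)", 0.0, k - 1, 1.0,
                                "monte_carlo", pw,
                                {nm: "a" for nm in names})

    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts ** 3 - counts).sum() / (n ** 3 - n)
    h_obs = float(_kw_statistic_from_ranks(ranks[None, :], sizes, tie_corr)[0])

    perm = rng.permuted(np.tile(ranks, (n_mc, 1)), axis=1)
    h_perm = _kw_statistic_from_ranks(perm, sizes, tie_corr)
    p = _mc_pvalue(h_perm, h_obs)

    # pairwise Mann-Whitney with the same permutation machinery
    k = len(gs)
    pw = None
    letters = {}
    if pairwise:
        pw = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
        for i in range(k):
            for j in range(i + 1, k):
                pij = _mw_mc_pair(gs[i], gs[j], n_mc, rng)
                if bonferroni:
                    pij = min(1.0, pij * k * (k - 1) / 2)
                pw.iloc[i, j] = pw.iloc[j, i] = pij
        medians = {nm: float(np.median(g)) for nm, g in zip(names, gs)}
        letters = assign_letters(medians, pw, alpha)
    return ComparisonResult("Kruskal-Wallis (MC)", h_obs, k - 1, p,
                            "monte_carlo", pw, letters)


def _mw_mc_pair(x: np.ndarray, y: np.ndarray, n_mc: int, rng) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    n = len(pooled)
    # two-sided via |U - n1 n2 / 2|
    def _u_dev(rank_rows):
        r1 = rank_rows[:, :n1].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        return np.abs(u - n1 * (n - n1) / 2.0)
    obs = float(_u_dev(ranks[None, :])[0])
    perm = rng.permuted(np.tile(ranks, (n_mc, 1)), axis=1)
    return _mc_pvalue(_u_dev(perm), obs)


def chi_squared_mc(contingency, n_mc: int = DEFAULT_N_MC, seed: int = 0) -> ComparisonResult:
    """Pearson chi-squared with a Monte-Carlo p-value (fixed margins).

    Reference tables are drawn conditionally on both margins
    (scipy.stats.random_table); p = (b + 1)/(m + 1).
    """
    table = np.asarray(pd.DataFrame(contingency), dtype=float)
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integer counts")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / table.sum()
    chi2_obs = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)

    rng = np.random.default_rng(seed)
    samples = stats.random_table(rows.astype(int), cols.astype(int)).rvs(
        n_mc, random_state=rng)
    chi2_perm = ((samples - expected) ** 2 / expected).sum(axis=(1, 2))
    p = _mc_pvalue(chi2_perm, chi2_obs)
    return ComparisonResult("chi-squared (MC)", chi2_obs, df, p, "monte_carlo")


def compare_across_clusters(values, labels, n_mc: int = DEFAULT_N_MC,
                            seed: int = 0, alpha: float = 0.05) -> ComparisonResult:
    """Route one variable through the decision tree used for cluster profiling.

    Levene screens variance homogeneity: homogeneous -> ANOVA + Tukey;
    heterogeneous -> Welch + Games-Howell. (The non-parametric MC route is
    available explicitly via :func:`kruskal_mw_mc` for strongly non-normal
    variables.)
    """
    labels = np.asarray(labels)
    y = np.asarray(values, dtype=float)
    uniq = np.unique(labels)
    gs = [y[labels == g] for g in uniq]
    names = [f"C{g}" for g in uniq]
    lev = levene_test(gs)
    if lev.p_value >= alpha:
        return anova_tukey(gs, names=names, alpha=alpha)
    return welch_games_howell(gs, names=names, alpha=alpha)
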