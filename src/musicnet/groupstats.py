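"""Inferential statistics for the expertise and state comparisons.

All tests return a :class:`StatResult` carrying the statistic, degrees of
freedom, two-sided p-value and an effect size.  The formulas are written out
explicitly (scipy distributions are used only for tail probabilities) so each
test can be checked against independent reference implementations.

Contents: unbalanced two-way ANOVA with Type-II sums of squares,
Tukey-Kramer post hoc for unequal group sizes, one-/two-sample and paired
t-tests with Cohen's d, exact Mann-Whitney U for small samples,
Benjamini-Hochberg FDR, edge-density checks, and the node-wise screen /
group-comparison workflow on nodal metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StatResult",
    "two_way_anova",
    "tukey_kramer",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "mann_whitney_u",
    "bh_fdr",
    "edge_density",
    "group_density_test",
    "nodal_one_sample_screen",
    "nodal_group_comparison",
]


@dataclass
class StatResult:
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    effect_size: float
    test_name: str
    n_per_group: tuple[int, ...] = ()

    def as_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "df": df,
            "p": float(self.p_value),
            "effect_size": float(self.effect_size),
            "n": list(self.n_per_group),
        }


# ---------------------------------------------------------------------------
# t-tests


def _t_result(t: float, df: float, d: float, name: str, ns) -> StatResult:
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(t, df, p, d, name, tuple(ns))


def one_sample_t(x, popmean: float = 0.0) -> StatResult:
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        return StatResult(np.inf if x.mean() != popmean else 0.0, n - 1,
                          np.nan, np.nan, "one_sample_t(zero_variance)", (n,))
    t = (x.mean() - popmean) / (sd / np.sqrt(n))
    d = (x.mean() - popmean) / sd
    return _t_result(t, n - 1, d, "one_sample_t", (n,))


def two_sample_t(a, b) -> StatResult:
    """Student's two-sample t with pooled SD; Cohen's d uses the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0:
        return StatResult(0.0, df, np.nan, np.nan,
                          "two_sample_t(zero_variance)", (na, nb))
    se = np.sqrt(sp2 * (1 / na + 1 / nb))
    t = (a.mean() - b.mean()) / se
    d = (a.mean() - b.mean()) / np.sqrt(sp2)
    return _t_result(t, df, d, "two_sample_t", (na, nb))


def paired_t(a, b) -> StatResult:
    """Paired t on a - b; Cohen's d = mean diff / SD of diffs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    n = len(diff)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    sd = diff.std(ddof=1)
    if sd == 0:
        return StatResult(0.0, n - 1, 1.0 if diff.mean() == 0 else np.nan,
                          0.0, "paired_t(zero_variance)", (n,))
    t = diff.mean() / (sd / np.sqrt(n))
    return _t_result(t, n - 1, diff.mean() / sd, "paired_t", (n,))


# ---------------------------------------------------------------------------
# Two-way ANOVA (Type-II) and Tukey-Kramer


def _dummies(f: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (first level dropped)."""
    levels = np.unique(f)
    return (f[:, None] == levels[None, 1:]).astype(float)


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of OLS y ~ X (X includes intercept)."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), rank


def two_way_anova(values, factor_condition, factor_state) -> dict[str, StatResult]:
    """Unbalanced two-way ANOVA with Type-II sums of squares.

    Each main effect is tested against the additive model lacking it
    (SS(A|B) = RSS(B) - RSS(A+B)); the interaction against the additive
    model.  The error term is the full-model MSE.  Returns StatResults keyed
    ``condition``, ``state``, ``interaction``.
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_condition)
    fb = np.asarray(factor_state)
    if len(np.unique(fa)) < 2 or len(np.unique(fb)) < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
    if (cells.to_numpy() == 0).any():
        raise ValueError("empty cell in condition x state design")

    ones = np.ones((len(y), 1))
    A = _dummies(fa)
    B = _dummies(fb)
    AB = np.concatenate(
        [(A[:, i] * B[:, j])[:, None] for i in range(A.shape[1]) for j in range(B.shape[1])],
        axis=1,
    )
    X_full = np.concatenate([ones, A, B, AB], axis=1)
    X_add = np.concatenate([ones, A, B], axis=1)
    X_a = np.concatenate([ones, A], axis=1)
    X_b = np.concatenate([ones, B], axis=1)

    rss_full, rank_full = _rss(y, X_full)
    rss_add, _ = _rss(y, X_add)
    rss_a, _ = _rss(y, X_a)
    rss_b, _ = _rss(y, X_b)

    df_a = A.shape[1]
    df_b = B.shape[1]
    df_ab = AB.shape[1]
    df_err = len(y) - rank_full
    mse = rss_full / df_err

    out: dict[str, StatResult] = {}
    for name, ss, dfn in (
        ("condition", rss_b - rss_add, df_a),
        ("state", rss_a - rss_add, df_b),
        ("interaction", rss_add - rss_full, df_ab),
    ):
        ss = max(ss, 0.0)
        if mse == 0:
            out[name] = StatResult(0.0, (dfn, df_err), np.nan, np.nan,
                                   f"anova_{name}(zero_residual)", (len(y),))
            continue
        F = (ss / dfn) / mse
        p = stats.f.sf(F, dfn, df_err)
        # partial eta squared as effect size
        eta = ss / (ss + rss_full) if (ss + rss_full) > 0 else 0.0
        out[name] = StatResult(F, (dfn, df_err), p, eta, f"anova_{name}", (len(y),))
    return out


def tukey_kramer(group_means, group_ns, mse: float, df_error: float) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons for unequal sample sizes.

    q_ij = |m_i - m_j| / sqrt(mse/2 * (1/n_i + 1/n_j)); p from the
    studentized range distribution with k groups and df_error.
    """
    means = np.asarray(group_means, dtype=float)
    ns = np.asarray(group_ns, dtype=int)
    if len(means) < 2:
        raise ValueError("need at least 2 groups")
    if (ns < 2).any():
        raise ValueError("each group needs n >= 2")
    if mse <= 0:
        raise ValueError("mse must be positive")
    k = len(means)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append({"group_i": i, "group_j": j, "mean_diff": means[i] - means[j],
                         "q": q, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_count_distribution(n1: int, n2: int) -> np.ndarray:
    """Number of rank arrangements giving each U value (no ties).

    Classic recursion: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u);
    returned as an array over u = 0..n1*n2.
    """
    max_u = n1 * n2
    # table[i][j] = polynomial coefficients over u for i,j group sizes
    prev = [np.array([1.0])]  # n1=0 row: U always 0
    for j in range(1, n2 + 1):
        prev.append(np.array([1.0]))
    for i in range(1, n1 + 1):
        cur = [np.array([1.0])]
        for j in range(1, n2 + 1):
            a = np.zeros(i * j + 1)
            left = prev[j]  # f(i-1, j, u-j)
            a[j : j + len(left)] += left
            down = cur[j - 1]  # f(i, j-1, u)
            a[: len(down)] += down
            cur.append(a)
        prev = cur
    counts = prev[n2]
    assert len(counts) == max_u + 1
    return counts


def mann_whitney_u(a, b, exact_max_n: int = 20) -> StatResult:
    """Mann-Whitney U; exact p for small untied samples, else normal approx.

    The reported statistic is min(U_a, U_b).  Two-sided exact p enumerates
    the null distribution of U over all rank assignments; the approximate
    branch applies the tie-corrected normal approximation with continuity
    correction.  Effect size is the rank-biserial correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u = min(u_a, u_b)
    has_ties = len(np.unique(combined)) < na + nb
    if not has_ties and na + nb <= exact_max_n:
        counts = _u_count_distribution(na, nb)
        total = counts.sum()
        p = 2.0 * counts[: int(round(u)) + 1].sum() / total
        p = min(p, 1.0)
        name = "mann_whitney_u_exact"
    else:
        mu = na * nb / 2.0
        n = na + nb
        _, tie_counts = np.unique(combined, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma = np.sqrt(na * nb / 12.0 * ((n + 1) - tie_term))
        if sigma == 0:
            return StatResult(u, np.nan, 1.0, 0.0,
                              "mann_whitney_u_approx(degenerate)", (na, nb))
        z = (u - mu + 0.5) / sigma  # continuity-corrected, lower tail
        p = min(2.0 * stats.norm.cdf(z), 1.0)
        name = "mann_whitney_u_approx"
    rbc = 1.0 - 2.0 * u / (na * nb)  # rank-biserial magnitude
    return StatResult(u, np.nan, p, rbc, name, (na, nb))


# ---------------------------------------------------------------------------
# FDR and density


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and survivor mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    q_values = np.empty(m)
    q_values[order] = adj
    survives = q_values <= q
    return q_values, survives


def edge_density(matrix: np.ndarray) -> float:
    """Fraction of the N(N-1)/2 unique edges with nonzero weight."""
    W = np.asarray(matrix)
    n = W.shape[0]
    iu = np.triu_indices(n, k=1)
    return float((W[iu] != 0).mean())


def group_density_test(densities_a, densities_b) -> StatResult:
    """Two-sample t on edge densities across groups (control analysis)."""
    return two_sample_t(densities_a, densities_b)


# ---------------------------------------------------------------------------
# Nodal workflow


def nodal_one_sample_screen(values: np.ndarray, q: float = 0.05) -> pd.DataFrame:
    """Per-node one-sample t against 0 across subjects, BH-FDR across nodes.

    ``values`` is subjects x nodes.  Returns one row per node with mean, t,
    p, q and the survivor flag.
    """
    values = np.asarray(values, dtype=float)
    rows = []
    for i in range(values.shape[1]):
        res = one_sample_t(values[:, i])
        rows.append({"node": i, "mean": values[:, i].mean(),
                     "t": res.statistic, "p": res.p_value})
    df = pd.DataFrame(rows)
    p = df["p"].fillna(1.0).to_numpy()
    df["q"], df["survives"] = bh_fdr(p, q=q)
    return df


def nodal_group_comparison(
    values_a: np.ndarray,
    values_b: np.ndarray,
    survivor_nodes,
    q: float = 0.05,
) -> pd.DataFrame:
    """Two-sample t per surviving node, BH-FDR across the tested nodes.

    ``values_a`` / ``values_b`` are subjects x nodes for the two groups;
    ``survivor_nodes`` indexes the nodes that passed the one-sample screen.
    """
    nodes = np.asarray(survivor_nodes, dtype=int)
    rows = []
    for i in nodes:
        res = two_sample_t(values_a[:, i], values_b[:, i])
        rows.append({"node": int(i), "t": res.statistic, "p": res.p_value,
                     "effect_size": res.effect_size})
    df = pd.DataFrame(rows)
    if df.empty:
        df["q"] = []
        df["survives"] = []
        return df
    df["q"], df["survives"] = bh_fdr(df["p"].fillna(1.0).to_numpy(), q=q)
    return df
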