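"""Nonparametric group comparisons used throughout the analyses.

Kruskal-Wallis one-way ANOVA on ranks (tie-corrected H) with Dunn's
pairwise post-hoc z tests (uncorrected by default, matching the
"uncorrected Dunn's multiple comparisons" convention), the Mann-Whitney U
test with exact enumeration for small samples (handling ties) and a
tie-corrected normal approximation otherwise, and a thin two-way
ANOVA + Fisher's LSD routine for factorial designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "KruskalDunnResult",
    "MannWhitneyResult",
    "kruskal_dunn",
    "mann_whitney",
    "anova_two_way_lsd",
]

_EXACT_LIMIT = 200_000  # max enumerated assignments for exact tests


@dataclass(frozen=True)
class KruskalDunnResult:
    h_statistic: float
    p_omnibus: float
    p_method: str
    pairwise: pd.DataFrame  # group_a, group_b, z, p (and p_adj when corrected)


@dataclass(frozen=True)
class MannWhitneyResult:
    u_statistic: float
    p_two_sided: float
    method: str


def _rank_sums_h(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled ranks split by group sizes."""
    n_total = ranks.size
    h = 0.0
    start = 0
    for n_i in sizes:
        r_i = ranks[start : start + n_i].sum()
        h += r_i * r_i / n_i
        start += n_i
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    denom = 1.0 - tie_term / (n_total**3 - n_total)
    if denom <= 0:
        return 0.0  # all values identical
    return h / denom


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _n_assignments(sizes: list[int]) -> int:
    total = sum(sizes)
    out = 1
    for n_i in sizes[:-1]:
        out *= math.comb(total, n_i)
        total -= n_i
    return out


def _exact_kruskal_p(pooled_ranks: np.ndarray, sizes: list[int], tie_term: float,
                     h_observed: float) -> float:
    """Exhaustive-enumeration p: fraction of assignments with H >= observed."""
    n_total = pooled_ranks.size
    indices = tuple(range(n_total))
    count_ge = 0
    n_assign = 0

    def recurse(remaining: tuple[int, ...], group: int, acc: list[np.ndarray]):
        nonlocal count_ge, n_assign
        if group == len(sizes) - 1:
            acc.append(pooled_ranks[list(remaining)])
            ranks = np.concatenate(acc)
            h = _rank_sums_h(ranks, sizes, tie_term)
            n_assign += 1
            if h >= h_observed - 1e-9:
                count_ge += 1
            acc.pop()
            return
        for combo in itertools.combinations(remaining, sizes[group]):
            rest = tuple(i for i in remaining if i not in set(combo))
            acc.append(pooled_ranks[list(combo)])
            recurse(rest, group + 1, acc)
            acc.pop()

    recurse(indices, 0, [])
    return count_ge / n_assign


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    p_method: str = "asymptotic",
    correction: str = "none",
) -> KruskalDunnResult:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post-hoc comparisons.

    Parameters
    ----------
    groups :
        Mapping from group label to 1-D numeric samples; >= 2 groups.
    p_method :
        'asymptotic' (chi-squared, default), 'exact' (exhaustive enumeration
        of rank assignments; only feasible for small pooled samples) or
        'auto' (exact when the assignment count is small enough).
    correction :
        'none' (uncorrected Dunn p-values, default) or 'bonferroni'.

    All-identical data yields the degenerate result H = 0, p = 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [np.asarray(groups[g], dtype=float).ravel() for g in labels]
    if any(s.size < 1 for s in samples):
        raise ValueError("each group needs >= 1 value")
    pooled = np.concatenate(samples)
    if np.unique(pooled).size < 2:
        pairwise = pd.DataFrame(
            [
                {"group_a": a, "group_b": b, "z": 0.0, "p": 1.0}
                for a, b in itertools.combinations(labels, 2)
            ]
        )
        return KruskalDunnResult(0.0, 1.0, "degenerate", pairwise)

    sizes = [s.size for s in samples]
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    tie_term = _tie_term(pooled)
    h = _rank_sums_h(ranks, sizes, tie_term)

    if p_method == "auto":
        p_method = "exact" if _n_assignments(sizes) <= _EXACT_LIMIT else "asymptotic"
    if p_method == "asymptotic":
        p_omnibus = float(sps.chi2.sf(h, df=len(labels) - 1))
    elif p_method == "exact":
        if _n_assignments(sizes) > _EXACT_LIMIT:
            raise ValueError(
                f"{_n_assignments(sizes)} assignments exceed the exact-test limit"
            )
        p_omnibus = _exact_kruskal_p(ranks, sizes, tie_term, h)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    # Dunn's z from the pooled-rank variance with tie correction
    variance = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    mean_ranks = {}
    start = 0
    for g, n_i in zip(labels, sizes):
        mean_ranks[g] = ranks[start : start + n_i].mean()
        start += n_i
    rows = []
    for a, b in itertools.combinations(labels, 2):
        n_a, n_b = samples[labels.index(a)].size, samples[labels.index(b)].size
        se = math.sqrt(variance * (1.0 / n_a + 1.0 / n_b))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p": min(p, 1.0)})
    pairwise = pd.DataFrame(rows)
    if correction == "bonferroni":
        pairwise["p_adj"] = np.minimum(pairwise["p"] * len(rows), 1.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    return KruskalDunnResult(h, p_omnibus, p_method, pairwise)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def mann_whitney(a, b, exact_max_n: int = 8) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    For samples with at most ``exact_max_n`` values each, the null
    distribution of U is enumerated exhaustively over all group assignments
    of the pooled values (ties handled by half-counting), and the two-sided
    p is ``min(1, 2 * min(P(U <= u), P(U >= u)))``.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n_a, n_b = a.size, b.size

    if n_a <= exact_max_n and n_b <= exact_max_n:
        pooled = np.concatenate([a, b])
        n_total = pooled.size
        u_values = np.array(
            [
                _u_statistic(
                    pooled[list(combo)],
                    pooled[[i for i in range(n_total) if i not in set(combo)]],
                )
                for combo in itertools.combinations(range(n_total), n_a)
            ]
        )
        p_le = float(np.mean(u_values <= u + 1e-12))
        p_ge = float(np.mean(u_values >= u - 1e-12))
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(u, p, "exact")

    mu = n_a * n_b / 2.0
    tie_term = _tie_term(np.concatenate([a, b]))
    n_total = n_a + n_b
    sigma2 = (n_a * n_b / 12.0) * (
        (n_total + 1) - tie_term / (n_total * (n_total - 1))
    )
    if sigma2 <= 0:
        return MannWhitneyResult(u, 1.0, "normal")
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u, p, "normal")


def anova_two_way_lsd(
    data: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
) -> dict:
    """Two-way ANOVA with uncorrected Fisher's-LSD pairwise comparisons.

    A thin standard routine for factorial designs (e.g. substrate rigidity x
    coating): ordinary least squares with interaction, type-II ANOVA table,
    and pairwise t tests between cell means using the residual mean square.
    Returns ``{"anova": DataFrame, "pairwise": DataFrame}``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = data[[value, factor_a, factor_b]].dropna().copy()
    model = smf.ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=frame
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    cells = frame.groupby([factor_a, factor_b])[value].agg(["mean", "count"])
    mse = model.mse_resid
    df_resid = model.df_resid
    rows = []
    for (ka, kb) in itertools.combinations(cells.index, 2):
        m1, n1 = cells.loc[ka]
        m2, n2 = cells.loc[kb]
        se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(t), df_resid)
        rows.append({"cell_a": ka, "cell_b": kb, "t": t, "p": min(p, 1.0)})
    return {"anova": anova, "pairwise": pd.DataFrame(rows)}
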