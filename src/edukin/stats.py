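"""Descriptive and nonparametric inferential statistics for LI/count data.

Group summaries are mean +/- SEM per regeneration stage.  Differences
between stages are tested with the omnibus Kruskal-Wallis test followed by
pairwise Mann-Whitney tests, as is conventional for small groups of
specimens (4-16 per stage) whose labeling indices need not be normal.

Small samples get exact permutation p-values: full enumeration for the
Kruskal-Wallis test when the pooled sample size is at most 10, and the
exact Mann-Whitney distribution when the two groups total at most 12 and
are tie-free.  Larger samples fall back to the usual tie-corrected
chi-square / normal approximations (with continuity correction for
Mann-Whitney).  Pairwise tests are flagged at a stringent default
``alpha = 0.005`` with no multiplicity correction (Holm and Bonferroni are
available but off by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EmptyPopulationError, ParameterError

__all__ = [
    "GroupSummary",
    "TestResult",
    "labeling_index",
    "summarize_groups",
    "kruskal_wallis",
    "mann_whitney",
    "mann_whitney_pairwise",
    "EXACT_KRUSKAL_MAX_N",
    "EXACT_MANNWHITNEY_MAX_N",
]

#: largest pooled sample size for which the Kruskal-Wallis p is enumerated
EXACT_KRUSKAL_MAX_N = 10
#: largest n1+n2 for which the Mann-Whitney p uses the exact distribution
EXACT_MANNWHITNEY_MAX_N = 12


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SEM of one group; SEM is NaN-flagged for n = 1."""

    group_label: str
    n: int
    mean: float
    sem: float


@dataclass(frozen=True)
class TestResult:
    """Statistic (H or U), its p-value and how the p-value was obtained."""

    statistic: float
    p_value: float
    method: str  # exact_permutation | chi_square_approx | normal_approx
    tie_corrected: bool


def labeling_index(n_labeled: int, n_total: int) -> float:
    """LI = 100 * n_labeled / n_total, percent."""
    if n_total <= 0:
        raise EmptyPopulationError("labeling index undefined for n_total <= 0")
    if not (0 <= n_labeled <= n_total):
        raise ParameterError(
            f"n_labeled must be in [0, n_total], got {n_labeled}/{n_total}"
        )
    return 100.0 * n_labeled / n_total


def summarize_groups(
    values_by_group: dict,
) -> pd.DataFrame:
    """Per-group n, mean and SEM as a table (one row per group).

    SEM uses the sample standard deviation (ddof=1) and is NaN for n = 1.
    """
    rows = []
    for label, vals in values_by_group.items():
        v = np.asarray(list(vals), dtype=float)
        if v.size == 0:
            raise EmptyPopulationError(f"group {label!r} is empty")
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(
            GroupSummary(group_label=str(label), n=int(v.size), mean=float(v.mean()), sem=sem)
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _kruskal_h(ranks: np.ndarray, group_sizes: Sequence[int], tie_factor: float) -> float:
    """Tie-corrected Kruskal-Wallis H from pooled mid-ranks split by group."""
    n = ranks.size
    h = 0.0
    start = 0
    for g in group_sizes:
        rsum = ranks[start : start + g].sum()
        h += rsum * rsum / g
        start += g
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_factor if tie_factor > 0 else 0.0


def _tie_factor(pooled: np.ndarray) -> float:
    n = pooled.size
    _, counts = np.unique(pooled, return_counts=True)
    return 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n)


def _exact_kruskal_p(pooled: np.ndarray, group_sizes: Sequence[int], h_obs: float) -> float:
    """Exact permutation p-value by full enumeration of group assignments.

    Observations are distinguishable; the pooled mid-ranks are fixed, only
    their partition into groups varies.  Recursion over index combinations
    enumerates each distinct assignment exactly once.
    """
    ranks = sps.rankdata(pooled)
    tie = _tie_factor(pooled)
    n = pooled.size
    tol = 1e-9

    count_ge = 0
    total = 0

    def recurse(remaining: tuple, sizes: Sequence[int], assigned_ranks: list):
        nonlocal count_ge, total
        if not sizes:
            h = _kruskal_h(np.concatenate(assigned_ranks), group_sizes, tie)
            total += 1
            if h >= h_obs - tol:
                count_ge += 1
            return
        g, rest = sizes[0], sizes[1:]
        if not rest:  # last group takes everything left
            recurse((), rest, assigned_ranks + [ranks[list(remaining)]])
            return
        for pick in combinations(remaining, g):
            left = tuple(i for i in remaining if i not in set(pick))
            recurse(left, rest, assigned_ranks + [ranks[list(pick)]])

    recurse(tuple(range(n)), tuple(group_sizes), [])
    return count_ge / total


def kruskal_wallis(groups: Sequence[Sequence[float]], exact: str = "auto") -> TestResult:
    """Kruskal-Wallis omnibus test across two or more groups.

    The tie-corrected H statistic follows the standard rank-sum formula.
    The p-value is an exact full-enumeration permutation p when the pooled
    size is at most ``EXACT_KRUSKAL_MAX_N`` (or ``exact=True``), otherwise
    the chi-square approximation with k-1 degrees of freedom.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ParameterError("need at least 2 groups")
    if any(g.size == 0 for g in gs):
        raise EmptyPopulationError("all groups must be non-empty")
    pooled = np.concatenate(gs)
    sizes = [g.size for g in gs]
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "exact_permutation", True)
    tie = _tie_factor(pooled)
    ranks = sps.rankdata(pooled)
    h_obs = _kruskal_h(ranks, sizes, tie)
    use_exact = exact is True or (exact == "auto" and pooled.size <= EXACT_KRUSKAL_MAX_N)
    if use_exact:
        p = _exact_kruskal_p(pooled, sizes, h_obs)
        return TestResult(float(h_obs), float(p), "exact_permutation", True)
    # large-sample chi-square, as scipy computes it
    h_scipy, p = sps.kruskal(*gs)
    return TestResult(float(h_scipy), float(p), "chi_square_approx", True)


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def mann_whitney(
    g1: Sequence[float],
    g2: Sequence[float],
    alternative: str = "two_sided",
) -> TestResult:
    """Mann-Whitney U test between two groups.

    Exact p (full null distribution of U) when the pooled size is at most
    ``EXACT_MANNWHITNEY_MAX_N`` and the data are tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.  The
    statistic reported is U for the first group.
    """
    if alternative not in _ALTERNATIVES:
        raise ParameterError(f"alternative must be one of {tuple(_ALTERNATIVES)}")
    a = np.asarray(list(g1), dtype=float)
    b = np.asarray(list(g2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyPopulationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    use_exact = tie_free and pooled.size <= EXACT_MANNWHITNEY_MAX_N
    res = sps.mannwhitneyu(
        a,
        b,
        alternative=_ALTERNATIVES[alternative],
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact_permutation" if use_exact else "normal_approx",
        tie_corrected=not use_exact,
    )


def mann_whitney_pairwise(
    groups: dict,
    alternative: str = "two_sided",
    alpha: float = 0.005,
    correction: Optional[str] = None,
):
    """All pairwise Mann-Whitney tests with significance flags.

    Parameters
    ----------
    groups : dict mapping label -> values
    alpha : float
        Flagging threshold on the (possibly adjusted) p-value; the default
        0.005 is deliberately stringent for un-corrected pairwise testing.
    correction : {None, "bonferroni", "holm"}
        Optional multiplicity adjustment (off by default: raw pairwise p
        at a stringent alpha is the convention this package follows).

    Returns
    -------
    (results, p_matrix, significant) where ``results`` maps each ordered
    label pair to its :class:`TestResult` and the two DataFrames are
    symmetric label-indexed matrices of p-values and boolean flags.
    """
    if correction not in (None, "bonferroni", "holm"):
        raise ParameterError("correction must be None, 'bonferroni' or 'holm'")
    labels = list(groups)
    results = {}
    pairs = list(combinations(labels, 2))
    pvals = []
    for l1, l2 in pairs:
        r = mann_whitney(groups[l1], groups[l2], alternative=alternative)
        results[(l1, l2)] = r
        pvals.append(r.p_value)
    adj = np.asarray(pvals, dtype=float)
    if correction == "bonferroni" and adj.size:
        adj = np.minimum(adj * adj.size, 1.0)
    elif correction == "holm" and adj.size:
        order = np.argsort(adj)
        stepped = np.maximum.accumulate(adj[order] * (adj.size - np.arange(adj.size)))
        adj = np.empty_like(stepped)
        adj[order] = np.minimum(stepped, 1.0)
    p_matrix = pd.DataFrame(np.ones((len(labels), len(labels))), index=labels, columns=labels)
    sig = pd.DataFrame(False, index=labels, columns=labels)
    for (l1, l2), p in zip(pairs, adj):
        p_matrix.loc[l1, l2] = p_matrix.loc[l2, l1] = p
        sig.loc[l1, l2] = sig.loc[l2, l1] = bool(p <= alpha)
    return results, p_matrix, sig
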