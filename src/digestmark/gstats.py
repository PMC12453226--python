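"""Nonparametric comparison of digestibility methods.

Digestibility values per trait are compared across the four determination
methods (total collection and the three markers) with a Kruskal–Wallis test
followed by Dunn's pairwise test on pooled midranks with tie correction and
multiplicity adjustment, summarised as a compact letter display.  A pooled
SEM and Shapiro–Wilk normality checks support the reporting table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "normality_check",
    "dunn_test",
    "kruskal_dunn",
    "sem_pooled",
    "compact_letters",
    "ComparisonResult",
]


def normality_check(values) -> tuple[float, float]:
    """Shapiro–Wilk statistic and p-value; requires 3 <= n <= 5000."""
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000 (n={v.size})")
    if float(np.ptp(v)) == 0.0:
        raise ValueError("normality check undefined for constant input")
    res = stats.shapiro(v)
    return float(res.statistic), float(res.pvalue)


def dunn_test(groups: dict[str, np.ndarray], adjustment: str = "bonferroni"
              ) -> pd.DataFrame:
    """Dunn's pairwise z tests on pooled midranks with tie correction.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with ``T = sum(t^3 - t)`` over tie groups; two-sided normal p-values are
    adjusted by the requested method over all pairs.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, arr in zip(names, arrays):
        mean_ranks[name] = float(ranks[start:start + arr.size].mean())
        start += arr.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    rows = []
    for a, b in combinations(names, 2):
        na, nb = groups[a].__len__(), groups[b].__len__()
        var = base_var * (1.0 / na + 1.0 / nb)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p_raw": p})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = multipletests(frame["p_raw"], method=adjustment)[1]
    else:
        frame["p_adj"] = []
    return frame


def compact_letters(
    names: list[str],
    means: dict[str, float],
    nonsignificant: set[tuple[str, str]],
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups sharing a letter are not significantly different.  Groups are
    lettered in descending order of their means (the largest mean gets 'a').
    """
    ordered = sorted(names, key=lambda n: -means[n])

    def ns(a: str, b: str) -> bool:
        return (a, b) in nonsignificant or (b, a) in nonsignificant

    letter_sets: list[set[str]] = []
    for g in ordered:
        placed = False
        for s in letter_sets:
            if g in s:
                placed = True
                continue
            if all(ns(g, other) for other in s):
                s.add(g)
                placed = True
        if not placed:
            # create a new letter containing g and everything ns with g
            newset = {g}
            for other in ordered:
                if other != g and ns(g, other) and all(
                    ns(other, member) for member in newset
                ):
                    newset.add(other)
            letter_sets.append(newset)
    # absorb: drop sets fully contained in another
    pruned = []
    for s in letter_sets:
        if not any(s < t for t in letter_sets if t is not s):
            if s not in pruned:
                pruned.append(s)
    # order letters by the best mean they contain
    pruned.sort(key=lambda s: min(ordered.index(g) for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in names}
    for letter, s in zip(alphabet, pruned):
        for g in ordered:
            if g in s:
                out[g] += letter
    return out


@dataclass
class ComparisonResult:
    """Kruskal–Wallis + Dunn comparison of one trait across methods."""

    trait: str
    means: dict[str, float]
    sem: float
    h: float
    p: float
    pairwise: pd.DataFrame
    letters: dict[str, str]


def sem_pooled(groups: dict[str, np.ndarray]) -> float:
    """Pooled SEM: sqrt(pooled within-group variance / harmonic mean n)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups for a pooled SEM")
    for name, arr in zip(groups, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
    num = sum((a.size - 1) * a.var(ddof=1) for a in arrays)
    den = sum(a.size - 1 for a in arrays)
    pooled_var = num / den
    harm_n = len(arrays) / sum(1.0 / a.size for a in arrays)
    return float(np.sqrt(pooled_var / harm_n))


def kruskal_dunn(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
    trait: str = "",
) -> ComparisonResult:
    """Kruskal–Wallis H with Dunn post-hoc letters for one trait."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    pooled = np.concatenate(list(arrays.values()))
    means = {k: float(v.mean()) for k, v in arrays.items()}
    if float(np.ptp(pooled)) == 0.0:
        # all values identical: nothing to separate
        names = list(arrays)
        pairwise = pd.DataFrame(
            [{"group_a": a, "group_b": b, "z": 0.0, "p_raw": 1.0, "p_adj": 1.0}
             for a, b in combinations(names, 2)]
        )
        return ComparisonResult(
            trait=trait, means=means, sem=sem_pooled(arrays), h=0.0, p=1.0,
            pairwise=pairwise, letters={k: "a" for k in names},
        )
    h, p = stats.kruskal(*arrays.values())
    pairwise = dunn_test(arrays, adjustment)
    nonsig = {
        (row["group_a"], row["group_b"])
        for _, row in pairwise.iterrows()
        if row["p_adj"] >= alpha
    }
    letters = compact_letters(list(arrays), means, nonsig)
    return ComparisonResult(
        trait=trait,
        means=means,
        sem=sem_pooled(arrays),
        h=float(h),
        p=float(p),
        pairwise=pairwise,
        letters=letters,
    )
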