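"""Nonparametric comparison of metrics and CWMs across land-use categories.

Kruskal–Wallis for an overall effect; pairwise Mann–Whitney (Wilcoxon
rank-sum) tests with Holm adjustment as post hoc; a compact letter
display (categories sharing a letter are not significantly different at
alpha) to mirror the letter annotations used on boxplots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


def _split_groups(values, groups) -> dict:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(v) != len(g):
        raise ValidationError("values and groups differ in length")
    out = {}
    for name in pd.unique(g):
        out[name] = v[g == name]
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    for name, arr in out.items():
        if len(arr) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 observations")
    return out


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) with chi-square p on k-1 df."""
    by_group = _split_groups(values, groups)
    arrays = list(by_group.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations identical: H = 0, no evidence of difference
        return 0.0, 1.0
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann–Whitney p: exact when both groups small and tie-free,
    normal approximation with continuity correction otherwise."""
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def compact_letter_display(categories: list, different: set[frozenset], alphabet: str = "abcdefghijklmnopqrstuvwxyz") -> dict:
    """Insert-and-absorb compact letter display.

    ``different`` holds the pairs judged significantly different; the
    returned mapping assigns each category a string of letters such that
    two categories share a letter iff their pair is NOT in ``different``.
    """
    sets: list[set] = [set(categories)]
    for pair in different:
        i, j = tuple(pair)
        for s in list(sets):
            if i in s and j in s:
                sets.remove(s)
                s1, s2 = s - {i}, s - {j}
                for cand in (s1, s2):
                    if cand and not any(cand <= other for other in sets):
                        sets.append(cand)
        # absorb: drop sets contained in another
        sets = [s for s in sets if not any(s < other for other in sets)]
    letters = {c: "" for c in categories}
    for letter, s in zip(alphabet, sets):
        for c in categories:
            if c in s:
                letters[c] += letter
    return letters


@dataclass
class GroupTestResult:
    response: str
    H: float
    p_kw: float
    pairwise_p: pd.DataFrame  # adjusted, symmetric
    letters: dict
    adjust: str = "holm"
    alpha: float = 0.05


def pairwise_wilcoxon(values, groups, adjust: str = "holm", alpha: float = 0.05,
                      response: str = "response") -> GroupTestResult:
    """Pairwise rank-sum tests with multiplicity adjustment and letters.

    ``adjust``: ``holm`` (default), ``bh`` (Benjamini–Hochberg) or
    ``none``.  The compact letter display is built from the adjusted
    p-values at ``alpha``.
    """
    by_group = _split_groups(values, groups)
    names = list(by_group.keys())
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    raw = [_rank_sum_p(by_group[a], by_group[b]) for a, b in pairs]
    if adjust == "none":
        adj = list(raw)
    elif adjust in ("holm", "bh"):
        method = "holm" if adjust == "holm" else "fdr_bh"
        adj = list(multipletests(raw, method=method)[1])
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    different = set()
    for (a, b), p in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = p
        if p < alpha:
            different.add(frozenset((a, b)))
    np.fill_diagonal(mat.values, np.nan)
    H, p_kw = kruskal_wallis(values, groups)
    letters = compact_letter_display(names, different)
    return GroupTestResult(response, H, p_kw, mat, letters, adjust, alpha)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="holm")[1]


def group_tests_table(profile_table: pd.DataFrame, responses: list[str],
                      adjust: str = "holm", alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run KW + post hoc for each response column against ``category``.

    Returns (tests table, letters table) in tidy form.
    """
    test_rows, letter_rows = [], []
    for resp in responses:
        res = pairwise_wilcoxon(profile_table[resp], profile_table["category"],
                                adjust=adjust, alpha=alpha, response=resp)
        test_rows.append({"response": resp, "H": res.H, "p": res.p_kw})
        for cat, let in res.letters.items():
            letter_rows.append({"response": resp, "category": cat, "letters": let})
    return pd.DataFrame(test_rows), pd.DataFrame(letter_rows)
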