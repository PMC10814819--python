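"""Statistical comparisons across storage days.

Replicate measurements are compared between days with the Mann–Whitney U
test (exact permutation p-value for small tie-free samples, normal
approximation with tie and continuity correction otherwise), or across all
days with one-way ANOVA followed by Tukey HSD, summarized as a compact
letter display (groups sharing a letter are not significantly different at
the chosen alpha).  Assay magnitudes are correlated pairwise (Pearson by
default, Spearman optionally).  The taste-acceptability rule combines
titratable acidity and soluble solids thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

DAY_ORDER = (1, 4, 6, 8, 11)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    group_sizes: tuple[int, ...]
    degenerate: bool = False


@dataclass(frozen=True)
class LetterDisplay:
    """Compact letter display: one letter string per group, in input order."""

    letters: tuple[str, ...]
    group_names: tuple[str, ...]


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann–Whitney U test of two independent samples.

    Uses the exact permutation distribution when the pooled sample has at
    most 16 tie-free observations, otherwise the normal approximation with
    tie and continuity corrections.  Two identical constant samples return
    p = 1 with a degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(
            statistic=len(x) * len(y) / 2.0,
            p_value=1.0,
            method="mann-whitney (degenerate)",
            group_sizes=(len(x), len(y)),
            degenerate=True,
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 16 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney ({method})",
        group_sizes=(len(x), len(y)),
    )


def compact_letter_display(
    pairwise_p: np.ndarray, alpha: float = 0.05, group_names: Sequence[str] | None = None
) -> LetterDisplay:
    """Insert-and-absorb compact letter display from a pairwise p-value matrix.

    Each letter corresponds to a set of groups with no significant pairwise
    difference; a pair shares a letter iff its p-value is >= alpha.
    """
    P = np.asarray(pairwise_p, dtype=float)
    k = P.shape[0]
    if P.shape != (k, k):
        raise ValueError("pairwise p-value matrix must be square")
    names = tuple(group_names) if group_names is not None else tuple(str(i) for i in range(k))

    # letter sets, each a frozenset of group indices with no internal
    # significant pair; start with one set containing everything and split
    # on each significant pair (insert), removing subsets (absorb)
    sets: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if P[i, j] < alpha:
                new_sets: list[set[int]] = []
                for s in sets:
                    if i in s and j in s:
                        new_sets.append(s - {i})
                        new_sets.append(s - {j})
                    else:
                        new_sets.append(s)
                # absorb: drop sets contained in another
                sets = [
                    s
                    for s in new_sets
                    if s and not any(s < t for t in new_sets if t is not s)
                ]
                # deduplicate
                uniq: list[set[int]] = []
                for s in sets:
                    if s not in uniq:
                        uniq.append(s)
                sets = uniq

    # letters ordered by the smallest member index for stable output
    sets.sort(key=lambda s: (min(s), -len(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for idx, s in enumerate(sets):
        ch = alphabet[idx] if idx < len(alphabet) else f"l{idx}"
        for g in s:
            letters[g] += ch
    return LetterDisplay(tuple(letters), names)


def anova_posthoc(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    group_names: Sequence[str] | None = None,
) -> tuple[TestResult, np.ndarray, LetterDisplay]:
    """One-way ANOVA, Tukey HSD pairwise p-values and compact letters.

    Degenerate input (zero variance everywhere) yields F undefined and
    letters assigned by mean ordering: identical means all share "a",
    distinct means are all declared different.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    names = (
        tuple(group_names)
        if group_names is not None
        else tuple(f"g{i}" for i in range(len(groups)))
    )
    k = len(groups)
    # zero within-group spread everywhere: F and Tukey are undefined
    if all(np.ptp(g) == 0.0 for g in groups):
        means = [g.mean() for g in groups]
        P = np.ones((k, k))
        for i in range(k):
            for j in range(k):
                if i != j and means[i] != means[j]:
                    P[i, j] = 0.0
        result = TestResult(np.nan, 1.0, "anova (degenerate)", tuple(len(g) for g in groups), True)
        return result, P, compact_letter_display(P, alpha, names)

    f_stat, p_val = stats.f_oneway(*groups)
    values = np.concatenate(groups)
    labels = np.concatenate([[names[i]] * len(g) for i, g in enumerate(groups)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    P = np.ones((k, k))
    order = {name: i for i, name in enumerate(tukey.groupsunique)}
    pos = [order[n] for n in names]  # tukey sorts group labels
    raw = np.asarray(tukey.pvalues)
    # pairwise_tukeyhsd enumerates pairs over its own sorted unique labels
    tk_pairs = list(itertools.combinations(range(k), 2))
    M = np.ones((k, k))
    for (a, b), p in zip(tk_pairs, raw):
        M[a, b] = M[b, a] = p
    for i in range(k):
        for j in range(k):
            P[i, j] = M[pos[i], pos[j]]
    result = TestResult(
        float(f_stat), float(p_val), "one-way anova + tukey hsd",
        tuple(len(g) for g in groups),
    )
    return result, P, compact_letter_display(P, alpha, names)


def pairwise_correlation(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    method: str = "pearson",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation matrix with two-sided p-values for the named columns.

    Zero-variance columns yield NaN correlations.  Requires >= 3 complete
    rows.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    data = table[cols].dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(k):
            xi = data[cols[i]].to_numpy(dtype=float)
            xj = data[cols[j]].to_numpy(dtype=float)
            if xi.std() == 0 or xj.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
            else:
                res = corr_fn(xi, xj)
                r[i, j], p[i, j] = float(res[0]), float(res[1])
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def acceptability_rule(ta_percent: float, tss_brix: float) -> bool:
    """Taste acceptability: titratable acidity <= 0.8 % and TSS >= 7 °Brix."""
    if ta_percent < 0 or tss_brix < 0:
        raise ValueError("TA and TSS must be non-negative")
    return ta_percent <= 0.8 and tss_brix >= 7.0


def day_comparison_report(
    table: pd.DataFrame,
    feature: str,
    day_column: str = "day",
    days: Sequence[int] = DAY_ORDER,
    holm: bool = False,
) -> pd.DataFrame:
    """Mann–Whitney tests between consecutive storage days for one feature.

    Raw p-values by default; Holm step-down adjustment behind the ``holm``
    flag.
    """
    if feature not in table.columns:
        raise KeyError(f"feature {feature!r} not in table")
    rows = []
    results = []
    for d0, d1 in zip(days[:-1], days[1:]):
        x = table.loc[table[day_column] == d0, feature].to_numpy(dtype=float)
        y = table.loc[table[day_column] == d1, feature].to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            missing = d0 if len(x) == 0 else d1
            raise ValueError(f"no rows for day {missing}")
        res = mann_whitney(x, y)
        results.append(res)
        rows.append(
            {
                "feature": feature,
                "day_a": d0,
                "day_b": d1,
                "U": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    report = pd.DataFrame(rows)
    if holm:
        report["p_holm"] = multipletests(report["p_value"], method="holm")[1]
    return report
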