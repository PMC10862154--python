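"""Two-group Mann-Whitney U comparison and fold-ratio reporting.

The U statistic is reported as min(U1, U2), so it tends towards 0 as the
overlap between the two groups' rank distributions vanishes.  The default
p-value is the normal approximation with continuity correction and tie
correction; an exact method (full enumeration of labelings, no ties) is also
provided.  No multiple-testing correction is applied across indices or sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from canalmorph.morphometry import INDEX_COLUMNS


@dataclass
class GroupComparison:
    """Result of one Mann-Whitney comparison."""

    U: float
    p: float
    n1: int
    n2: int
    method: str
    site: str | None = None
    index: str | None = None
    selection: str | None = None


def _midranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..N with mid-ranks for ties (first-principles implementation)."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        # positions i..j share the average of ranks i+1..j+1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups of the pooled sample."""
    _, counts = np.unique(values, return_counts=True)
    t = counts.astype(float)
    return float(((t**3) - t).sum())


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def mann_whitney(a, b, method: str = "asymptotic_cc", **labels) -> GroupComparison:
    """Mann-Whitney U test of two independent samples.

    Both samples are ranked jointly with mid-ranks for ties;
    U1 = R1 - n1(n1+1)/2 and U = min(U1, U2) is reported.

    method='asymptotic_cc' (default): z = (U - n1 n2 / 2 + 0.5) / sigma with
    the tie-corrected sigma, two-sided p = 2 Phi(z) capped at 1.  This is the
    convention whose printed p-values the comparison tables follow.

    method='exact': enumerate all C(N, n1) labelings of the pooled sample
    (ties not supported) and report p = 2 P(U' <= U) capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1
    u = min(u1, u2)

    if method == "asymptotic_cc":
        n = n1 + n2
        tie = _tie_term(pooled)
        var = n1 * n2 / 12.0 * ((n**3 - n) - tie) / (n * (n - 1))
        if var <= 0:  # all observations identical
            p = 1.0
        else:
            z = (u - n1 * n2 / 2.0 + 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * _norm_cdf(z))
    elif method == "exact":
        if len(np.unique(pooled)) != len(pooled):
            raise ValueError("exact method requires tie-free data")
        total = math.comb(n1 + n2, n1)
        count = 0
        pooled_ranks = _midranks(pooled)
        for combo in itertools.combinations(range(n1 + n2), n1):
            r = pooled_ranks[list(combo)].sum()
            u_prime = r - n1 * (n1 + 1) / 2.0
            if u_prime <= u:
                count += 1
        p = min(1.0, 2.0 * count / total)
    else:
        raise ValueError("method must be 'asymptotic_cc' or 'exact'")

    return GroupComparison(U=float(u), p=float(p), n1=n1, n2=n2, method=method,
                           **labels)


def fold_ratio(rested_mean: float, exercised_mean: float) -> float:
    """Rested/exercised fold ratio of a group-mean index.

    A zero denominator is flagged unbounded (returns inf).
    """
    if exercised_mean == 0:
        return math.inf
    if exercised_mean < 0:
        raise ValueError("exercised mean must be positive")
    return rested_mean / exercised_mean


def compare_groups(section_table: pd.DataFrame, method: str = "asymptotic_cc",
                   indices=INDEX_COLUMNS) -> pd.DataFrame:
    """Mann-Whitney comparisons per site x index x selection (comparisons.csv).

    ``section_table`` is a sections table with one row per section and
    ``group`` in {exercised, rested}; output rows are (site, selection) and
    columns U/p per index, mirroring the study's comparison tables.
    """
    rows = []
    for (site, selection), sub in section_table.groupby(["site", "selection"],
                                                        sort=True):
        row = {"site": site, "selection": selection}
        a = sub[sub["group"] == "exercised"]
        b = sub[sub["group"] == "rested"]
        if a.empty or b.empty:
            raise ValueError(f"site {site!r} lacks one of the two groups")
        for col in indices:
            res = mann_whitney(a[col].to_numpy(), b[col].to_numpy(), method=method)
            row[f"{col}_U"] = res.U
            row[f"{col}_p"] = res.p
        row["n_exercised"] = len(a)
        row["n_rested"] = len(b)
        rows.append(row)
    return pd.DataFrame(rows)
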