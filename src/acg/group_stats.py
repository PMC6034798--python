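"""Group comparison statistics: Fisher's exact test and Kruskal-Wallis.

Categorical covariates are compared with the two-sided Fisher exact test
under the probability-mass ordering (the R ``fisher.test`` convention:
sum the hypergeometric probabilities of every table, with the observed
margins fixed, that is no more probable than the observed one).
Quantitative features use the Kruskal-Wallis rank test with mid-rank tie
correction and the chi-square approximation for the p-value — standard at
the study's group sizes (22 and 75).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "GroupComparison",
    "fisher_exact_two_sided",
    "kruskal_wallis",
    "compare_groups",
    "format_p",
]

#: relative slack when comparing hypergeometric masses (R uses 1 + 1e-7)
_REL_ERR = 1.0 + 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group, columns = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table must contain at least one observation")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    per_group: Dict[str, str]
    test: str
    p_value: float


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*[int(x) for x in arr.ravel()])


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass ordering).

    With margins fixed, the first cell follows a hypergeometric
    distribution; the p-value sums the probabilities of all tables whose
    probability does not exceed the observed table's (within the customary
    1e-7 relative slack to absorb floating-point ties).
    """
    t = _as_table(table)
    n = t.a + t.b + t.c + t.d
    row1 = t.a + t.b
    col1 = t.a + t.c
    dist = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(t.a)
    return float(min(pmf[pmf <= p_obs * _REL_ERR].sum(), 1.0))


def kruskal_wallis(samples_by_group: Sequence[Sequence[float]]):
    """Kruskal-Wallis H and chi-square p-value over two or more groups.

    Mid-ranks for ties with the standard tie correction.  Degenerate input
    where every observation is identical gives (H, p) = (0, 1) by
    convention.
    """
    groups = [np.asarray(g, dtype=float) for g in samples_by_group]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def format_p(p: float) -> str:
    """p-value to two significant figures, as printed in study reports."""
    if p <= 0:
        return "0"
    return f"{p:.2g}"


def compare_groups(
    df: pd.DataFrame,
    group_col: str = "group",
    quantitative: Optional[Sequence[str]] = None,
    categorical: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Tabular group comparison in the study's report layout.

    Quantitative columns report per-group mean and SD with a Kruskal-Wallis
    p; categorical (binary) columns report counts and within-group
    percentages with a Fisher exact p.  Columns are auto-classified by
    dtype/values when not given explicitly.  Statistics depend only on the
    multiset of values per group, never on row order.
    """
    groups = list(pd.unique(df[group_col]))
    if len(groups) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    value_cols = [c for c in df.columns if c not in (group_col, "subject_id")]
    if quantitative is None and categorical is None:
        categorical = [
            c for c in value_cols if set(np.unique(df[c].dropna())) <= {0, 1}
        ]
        quantitative = [c for c in value_cols if c not in categorical]
    quantitative = list(quantitative or [])
    categorical = list(categorical or [])

    sub = {g: df[df[group_col] == g] for g in groups}
    rows = []
    for col in quantitative:
        samples = [sub[g][col].dropna().values for g in groups]
        h, p = kruskal_wallis(samples)
        row = {"variable": col, "test": "kruskal_wallis", "H": h}
        for g in groups:
            vals = sub[g][col].dropna()
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"{g}_mean"] = vals.mean()
            row[f"{g}_sd"] = sd
        row["p_value"] = p
        row["p_printed"] = format_p(p)
        rows.append(row)
    for col in categorical:
        counts = {g: int(sub[g][col].sum()) for g in groups}
        table = [
            [counts[groups[0]], len(sub[groups[0]]) - counts[groups[0]]],
            [counts[groups[1]], len(sub[groups[1]]) - counts[groups[1]]],
        ]
        p = fisher_exact_two_sided(table)
        row = {"variable": col, "test": "fisher_exact", "H": np.nan}
        for g in groups:
            n = len(sub[g])
            row[f"{g}_mean"] = counts[g]
            row[f"{g}_sd"] = 100.0 * counts[g] / n if n else np.nan
        row["p_value"] = p
        row["p_printed"] = format_p(p)
        rows.append(row)
    return pd.DataFrame(rows)
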