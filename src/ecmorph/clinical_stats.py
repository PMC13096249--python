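"""Cohort-characteristics statistics for two-group clinical tables.

Implements the comparison conventions used for baseline ("Table 1" style)
summaries of a two-group patient cohort:

* categorical variables: Pearson chi-square, or Fisher's exact test when any
  expected cell count is below five; for 2x2 tables the Fisher p-value is
  always reported alongside, because exact p-values are the convention for
  small clinical cohorts even when expectations exceed five;
* continuous variables: Mann-Whitney U (medians with interquartile ranges
  are the descriptive summary — cohort lab values are rarely normal);
* two-sided Fisher p-values follow the probability-mass definition: the sum
  of hypergeometric probabilities of all tables with the observed margins
  that are no more probable than the observed table.

The heavy lifting is delegated to :mod:`scipy.stats`; this module fixes the
conventions (test selection rule, exactness thresholds, p-value formatting)
and the tabular input/output shapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n: tuple = ()
    q_value: float | None = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class ContingencyTable:
    """2xk table of counts with group (row) and category (column) labels."""

    counts: np.ndarray
    row_labels: tuple = ("group_a", "group_b")
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != 2:
            raise ValueError("expected a 2xk table of counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ValueError("table has no observations")
        if not self.col_labels:
            self.col_labels = tuple(f"level_{j}" for j in range(self.counts.shape[1]))

    @property
    def expected(self) -> np.ndarray:
        """Expected counts under independence (row x column margins / N)."""
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        return r * c / self.counts.sum()


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    Uses the probability-mass definition of "as extreme": p is the total
    hypergeometric probability of all tables sharing the observed margins
    whose point probability does not exceed that of the observed table.
    """
    t = _as_table(table)
    if t.counts.shape != (2, 2):
        raise ValueError(
            "fisher_exact_2x2 requires a 2x2 table; use chi_square for 2xk"
        )
    odds, p = stats.fisher_exact(t.counts, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        method="fisher_exact",
        n=tuple(t.counts.sum(axis=1)),
    )


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square test of independence for a 2xk table.

    ``yates`` applies the continuity correction (2x2 tables only).
    """
    t = _as_table(table)
    if yates and t.counts.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    res = stats.chi2_contingency(t.counts, correction=yates)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="chi_square_yates" if yates else "chi_square",
        n=tuple(t.counts.sum(axis=1)),
    )


def select_test(table) -> str:
    """Choose between Fisher's exact test and chi-square for a 2xk table.

    Any expected cell count strictly below five selects ``"fisher"``;
    otherwise ``"chi_square"``. An expected count of exactly five keeps the
    asymptotic test.
    """
    t = _as_table(table)
    return "fisher" if (t.expected < 5).any() else "chi_square"


def categorical_test(table) -> TestResult:
    """Run the selected test for a 2xk categorical table.

    For 2x2 tables the Fisher exact p-value is reported regardless of the
    selection rule (the convention that matches exact reporting in small
    cohorts); the selection-rule choice is recorded in ``warnings`` when it
    differs. For 2xk (k > 2) tables with small expected counts, Fisher's
    exact test is approximated by chi-square with a warning (k-level exact
    tests are out of scope).
    """
    t = _as_table(table)
    choice = select_test(t)
    if t.counts.shape == (2, 2):
        res = fisher_exact_2x2(t)
        if choice == "chi_square":
            res.warnings.append(
                "selection rule prefers chi_square (all expected >= 5); "
                "Fisher p reported by convention"
            )
        return res
    res = chi_square(t)
    if choice == "fisher":
        res.warnings.append("expected counts < 5 in a 2xk table; chi-square used")
    return res


def mann_whitney_u(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p-value (full enumeration of rank assignments) when the combined
    sample size is at most 20 and there are no ties; normal approximation
    with tie and continuity corrections otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann_whitney_{method}",
        n=(a.size, b.size),
    )


def format_p(p: float) -> str:
    """Clinical-table p-value formatting: 3 decimals, '< 0.001' below."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


def _is_binary(series: pd.Series) -> bool:
    vals = set(pd.unique(series.dropna()))
    return vals <= {0, 1, True, False}


def summarise_cohort(cohort: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Build a Table-1-style summary of a two-group cohort.

    Binary (0/1) columns are summarised as ``n (%)`` per group and tested
    with the categorical rule of :func:`categorical_test`; numeric columns
    as ``median [q1-q3]`` (linear-interpolation quantiles) with
    Mann-Whitney U. Returns one row per variable with per-group summaries,
    the p-value, its display string and the test used.
    """
    groups = list(pd.unique(cohort[group_col]))
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    ga, gb = groups
    rows = []
    for col in cohort.columns:
        if col == group_col:
            continue
        sa = cohort.loc[cohort[group_col] == ga, col].dropna()
        sb = cohort.loc[cohort[group_col] == gb, col].dropna()
        if _is_binary(cohort[col]):
            ka, kb = int(sa.sum()), int(sb.sum())
            na, nb = len(sa), len(sb)
            tab = ContingencyTable(
                [[ka, na - ka], [kb, nb - kb]], row_labels=(ga, gb),
                col_labels=("yes", "no"),
            )
            res = categorical_test(tab)
            summ_a = f"{ka} ({100 * ka / na:.0f})"
            summ_b = f"{kb} ({100 * kb / nb:.0f})"
            kind = "categorical"
        else:
            qa = np.percentile(sa, [50, 25, 75])
            qb = np.percentile(sb, [50, 25, 75])
            res = mann_whitney_u(sa, sb)
            summ_a = f"{qa[0]:g} [{qa[1]:g}-{qa[2]:g}]"
            summ_b = f"{qb[0]:g} [{qb[1]:g}-{qb[2]:g}]"
            kind = "continuous"
        rows.append(
            {
                "variable": col,
                "kind": kind,
                str(ga): summ_a,
                str(gb): summ_b,
                "p_value": res.p_value,
                "p_display": format_p(res.p_value),
                "test": res.method,
            }
        )
    return pd.DataFrame(rows)
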