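"""Cohort balance checks.

Case–control comparisons are only interpretable when the groups are matched
on nuisance covariates; these helpers run the standard demographic balance
tests: a Pearson chi-square (no continuity correction, 1 df) for 2x2
categorical tables such as sex or handedness, and a two-sided Welch t-test
for continuous covariates such as age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["chi_square_2x2", "welch_t_test", "BalanceReport", "balance_report"]


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction.

    Returns (statistic, two-sided p) at 1 degree of freedom.  All margins
    must be positive (a zero margin makes the expected counts degenerate).
    """
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def welch_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if a.std() == 0 and b.std() == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return float(stat), float(p)


@dataclass
class BalanceReport:
    """Per-covariate test name, statistic and p-value."""

    rows: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    @property
    def balanced(self) -> bool:
        """True when no covariate differs at p < 0.05."""
        return all(row["p_value"] >= 0.05 for row in self.rows)


def balance_report(
    categorical: dict[str, np.ndarray] | None = None,
    continuous: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> BalanceReport:
    """Run balance tests over named covariates.

    ``categorical`` maps a name to a 2x2 count table; ``continuous`` maps a
    name to the two groups' value arrays.
    """
    rows = []
    for name, table in (categorical or {}).items():
        stat, p = chi_square_2x2(table)
        rows.append({"covariate": name, "test": "chi2_2x2",
                     "statistic": stat, "p_value": p})
    for name, (a, b) in (continuous or {}).items():
        stat, p = welch_t_test(a, b)
        rows.append({"covariate": name, "test": "welch_t",
                     "statistic": stat, "p_value": p})
    return BalanceReport(rows=rows)
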