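"""Summary statistics and Pearson correlation analysis.

Per-variable descriptives use the sample (n-1) standard deviation and
report the coefficient of variation in percent.  Correlations use
pairwise-complete deletion, because different variables are available for
different subsets of the literature records, with two-sided p-values from
the t statistic ``r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import Dataset


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    n: int
    mean: float
    minimum: float
    maximum: float
    sd: float
    cv: float  # percent, 100 * sd / mean


def summarize(dataset: Dataset, variables: Sequence[str]) -> list[SummaryRow]:
    """Per-variable n, mean, min, max, sample SD and CV (%).

    Raises
    ------
    ValueError
        If a variable has fewer than two non-missing values (named in the
        message).
    """
    rows = []
    for var in variables:
        x = dataset.column(var)
        x = x[~np.isnan(x)]
        if x.size < 2:
            raise ValueError(f"variable {var!r} has fewer than 2 non-missing values")
        sd = float(np.std(x, ddof=1))
        mean = float(np.mean(x))
        rows.append(SummaryRow(
            variable=var, n=int(x.size), mean=mean,
            minimum=float(np.min(x)), maximum=float(np.max(x)),
            sd=sd, cv=100.0 * sd / mean if mean != 0 else float("nan"),
        ))
    return rows


def summary_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summaries as a DataFrame mirroring the descriptive-table layout."""
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("variable")


@dataclass
class CorrelationTable:
    """Pairwise-complete Pearson correlations with p-values and counts."""

    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def correlations(
    dataset: Dataset, variables: Sequence[str], min_n: int = 3
) -> CorrelationTable:
    """Pearson correlation matrix on pairwise-complete cases.

    Cells with fewer than ``min_n`` complete pairs are left as NaN rather
    than fabricated.
    """
    variables = list(variables)
    m = len(variables)
    data = {v: dataset.column(v) for v in variables}
    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n = np.zeros((m, m), dtype=int)
    for i, vi in enumerate(variables):
        r[i, i] = 1.0
        p[i, i] = 0.0
        n[i, i] = int(np.sum(~np.isnan(data[vi])))
        for j in range(i + 1, m):
            xi, xj = data[vi], data[variables[j]]
            mask = ~np.isnan(xi) & ~np.isnan(xj)
            nij = int(mask.sum())
            n[i, j] = n[j, i] = nij
            if nij < min_n:
                continue
            res = stats.pearsonr(xi[mask], xj[mask])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    mk = lambda a: pd.DataFrame(a, index=variables, columns=variables)
    return CorrelationTable(variables, mk(r), mk(p), mk(n))
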