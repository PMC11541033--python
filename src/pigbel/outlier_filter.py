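"""Influence-based outlier screening.

Observations are screened once by Cook's distance on an ordinary
least-squares regression (by default BEL of crude protein on initial body
weight) and removed when the distance exceeds Fox's criterion
4 / (n - k - 1), where n is the number of complete cases and k the number
of predictors excluding the intercept.  The screen is a single pass:
distances are computed once and all exceedances removed together;
re-running the filter on its own output may legitimately remove more
points and is not done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core_data import Dataset


def fox_criterion(n: int, k: int) -> float:
    """Fox's cut-off for Cook's distance: ``4 / (n - k - 1)``.

    Parameters
    ----------
    n : int
        Number of observations entering the regression.
    k : int
        Number of predictors, excluding the intercept.
    """
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (got n={n}, k={k})")
    return 4.0 / (n - k - 1)


def cooks_distance(response: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Cook's distance for each observation of an OLS fit.

    ``design`` must include the intercept column.  Equals
    ``(e_i^2 / (p s^2)) * h_i / (1 - h_i)^2`` with residual e_i, leverage
    h_i, p estimated coefficients and residual mean square s^2, which is
    the scaled shift in fitted values when observation i is deleted.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} rows, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, X).fit()
    return np.asarray(fit.get_influence().cooks_distance[0])


@dataclass
class OutlierReport:
    """Outcome of one screening pass."""

    threshold: float
    distances: dict[int, float]       # dataset row index -> Cook's distance
    removed_ids: list[str]
    removed_indices: list[int]
    skipped_indices: list[int] = field(default_factory=list)  # incomplete rows, passed through
    n_before: int = 0
    n_after: int = 0

    def to_summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_before": self.n_before,
            "n_after": self.n_after,
            "n_removed": len(self.removed_indices),
            "n_skipped": len(self.skipped_indices),
            "removed_ids": list(self.removed_ids),
        }


def filter_outliers(
    dataset: Dataset,
    response: str = "bel_cp",
    predictors: tuple[str, ...] = ("ibw",),
) -> tuple[Dataset, OutlierReport]:
    """Single-pass Cook's distance filter against Fox's criterion.

    Distances are computed on the complete cases of (response, predictors);
    rows exceeding the threshold (strict ``>``; ties are kept) are dropped.
    Rows with any of the screening variables missing cannot be scored; they
    pass through untouched and are listed in ``skipped_indices``.

    Returns the filtered dataset (original order preserved) and a report.
    """
    k = len(predictors)
    cols = [dataset.column(response)] + [dataset.column(p) for p in predictors]
    mat = np.column_stack(cols)
    complete = ~np.isnan(mat).any(axis=1)
    idx = np.flatnonzero(complete)
    n = idx.size
    if n < k + 3:
        raise ValueError(
            f"outlier screen needs at least {k + 3} complete cases of "
            f"({response}, {', '.join(predictors)}), got {n}"
        )
    y = mat[idx, 0]
    X = sm.add_constant(mat[idx, 1:])
    distances = cooks_distance(y, X)
    threshold = fox_criterion(n, k)
    removed_mask = distances > threshold

    removed_indices = [int(i) for i in idx[removed_mask]]
    removed_set = set(removed_indices)
    kept = [obs for i, obs in enumerate(dataset) if i not in removed_set]
    report = OutlierReport(
        threshold=threshold,
        distances={int(i): float(d) for i, d in zip(idx, distances)},
        removed_ids=[dataset[i].study_id for i in removed_indices],
        removed_indices=removed_indices,
        skipped_indices=[int(i) for i in np.flatnonzero(~complete)],
        n_before=len(dataset),
        n_after=len(kept),
    )
    provenance = dataset.provenance + [
        f"filter_outliers: response={response}, predictors={predictors}, "
        f"threshold={threshold:.6g}, removed {len(removed_indices)} of {n} complete cases"
    ]
    return Dataset(kept, provenance), report
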