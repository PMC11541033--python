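"""Mean-bias / linear-bias evaluation of a prediction equation.

A candidate equation for BEL of crude protein is judged by regressing the
prediction error (measured minus predicted) on the mean-centered
predictions.  The intercept of that regression is the mean bias — the
average systematic offset of the equation — and the slope is the linear
bias — the tendency to over- or under-predict progressively more for
larger predicted values.  Both are reported with standard errors and
two-sided t tests on n - 2 degrees of freedom.
"""

from __future__ import annotations

import inspect
import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import statsmodels.api as sm

from .core_data import Dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasReport:
    mean_bias: float       # intercept, response units
    linear_bias: float     # slope, dimensionless
    se_mean_bias: float
    se_linear_bias: float
    p_mean_bias: float
    p_linear_bias: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def bias_regression(measured, predicted) -> BiasReport:
    """OLS of (measured - predicted) on (predicted - mean(predicted)).

    Raises
    ------
    ValueError
        If fewer than 3 pairs are supplied or the predictions are constant
        (the slope would be undefined).
    """
    m = np.asarray(measured, float)
    p = np.asarray(predicted, float)
    if m.shape != p.shape:
        raise ValueError("measured and predicted must have equal length")
    mask = ~(np.isnan(m) | np.isnan(p))
    m, p = m[mask], p[mask]
    n = m.size
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    centered = p - p.mean()
    if np.ptp(centered) == 0:
        raise ValueError("predicted values are constant; linear bias undefined")
    fit = sm.OLS(m - p, sm.add_constant(centered)).fit()
    return BiasReport(
        mean_bias=float(fit.params[0]), linear_bias=float(fit.params[1]),
        se_mean_bias=float(fit.bse[0]), se_linear_bias=float(fit.bse[1]),
        p_mean_bias=float(fit.pvalues[0]), p_linear_bias=float(fit.pvalues[1]),
        n=int(n),
    )


def _call_equation(equation: Callable, obs) -> float:
    """Invoke a user equation with whichever of (ibw, fi_mfi) it accepts."""
    try:
        params = inspect.signature(equation).parameters
    except (TypeError, ValueError):
        params = None
    if params is not None and "fi_mfi" not in params and len(params) < 2:
        return float(equation(obs.ibw))
    return float(equation(obs.ibw, obs.fi_mfi))


def evaluate_equation(
    dataset: Dataset,
    equation: Callable,
    subset: Callable[[object], bool] | None = None,
) -> BiasReport:
    """Apply a BEL-of-CP prediction equation and run the bias regression.

    ``equation`` is any callable taking ``(ibw)`` or ``(ibw, fi_mfi)`` and
    returning predicted BEL of CP (g/kg DMI); the package's own fitted
    models or published-equation wrappers both qualify.  ``subset``
    optionally restricts evaluation (e.g. to observations held out from an
    equation's training set).  Rows without a measured bel_cp, rows
    excluded by ``subset``, and rows where the equation raises are skipped
    with a log entry.
    """
    measured, predicted = [], []
    for obs in dataset:
        if obs.bel_cp is None or (subset is not None and not subset(obs)):
            continue
        try:
            pred = _call_equation(equation, obs)
        except Exception as exc:  # equation may be partial; skip and log
            logger.info("equation failed for %s: %s", obs.study_id, exc)
            continue
        measured.append(obs.bel_cp)
        predicted.append(pred)
    if len(measured) < 3:
        raise ValueError(
            f"only {len(measured)} usable observations; need at least 3"
        )
    return bias_regression(np.array(measured), np.array(predicted))
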