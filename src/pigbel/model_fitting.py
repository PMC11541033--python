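"""Regression model families for basal endogenous losses.

Three families describe BEL of crude protein as a function of initial body
weight (IBW) and, optionally, feeding level (FI:MFI):

* linear:        y = C1 + C2*x1 [+ C3*x2]
* exponential:   y = C1 * exp(C2*x1 [+ C3*x2]), least squares on the
  original scale, Gauss-Newton refinement started from the log-linearized
  ordinary-least-squares fit;
* one-slope broken line:  y = L + U*max(R - x, 0), a sloped segment
  meeting a constant plateau L at the breakpoint R.  The breakpoint is
  profiled out: for fixed R the model is linear in (L, U) and solves in
  closed form, and between consecutive observed x values the profile SSE
  is a smooth rational function of R whose stationary point also has a
  closed form, so the global minimum is found exactly by scanning every
  observed candidate plus every interior stationary point.

BEL of each amino acid is modelled as a simple linear function of BEL of
crude protein.

Conventions: RMSE = sqrt(SSE / (n - p)) on residual degrees of freedom;
R^2 = 1 - SSE/SST about the response mean for all families (may be
negative for a poor nonlinear fit); the overall p-value is from the F test
against the intercept-only model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_data import AA_CODES, Dataset

logger = logging.getLogger(__name__)

_COEF_NAMES = ("C1", "C2", "C3")


class ConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate and SSE trace."""

    def __init__(self, message: str, last_iterate: np.ndarray, sse_trace: list[float]):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.sse_trace = sse_trace


@dataclass
class ModelFit:
    """A fitted linear or exponential model.

    ``coefficients`` maps C1 (intercept or scale), C2 (first predictor) and
    optionally C3 (second predictor) to estimates; ``se`` holds matching
    standard errors; ``predictor_names`` records which variable each of
    C2/C3 multiplies.
    """

    family: str
    coefficients: dict[str, float]
    se: dict[str, float]
    predictor_names: tuple[str, ...]
    rmse: float
    r2: float
    p_model: float
    n: int
    sse: float = float("nan")

    @property
    def n_coefficients(self) -> int:
        return len(self.coefficients)

    def predict(self, *predictors: np.ndarray) -> np.ndarray:
        if len(predictors) != len(self.predictor_names):
            raise ValueError(
                f"model expects {len(self.predictor_names)} predictor(s): "
                f"{self.predictor_names}"
            )
        c = self.coefficients
        eta = sum(c[_COEF_NAMES[i + 1]] * np.asarray(x, float)
                  for i, x in enumerate(predictors))
        if self.family == "linear":
            return c["C1"] + eta
        return c["C1"] * np.exp(eta)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": self.coefficients,
            "se": self.se,
            "predictors": list(self.predictor_names),
            "rmse": self.rmse,
            "r2": self.r2,
            "p_model": self.p_model,
            "n": self.n,
        }


def _as_predictor_frame(predictors) -> pd.DataFrame:
    """Coerce one or two predictor vectors into a named DataFrame."""
    if isinstance(predictors, pd.DataFrame):
        frame = predictors.copy()
    elif isinstance(predictors, dict):
        frame = pd.DataFrame(predictors)
    elif isinstance(predictors, (list, tuple)):
        frame = pd.DataFrame({f"x{i + 1}": np.asarray(v, float)
                              for i, v in enumerate(predictors)})
    else:
        frame = pd.DataFrame({"x1": np.asarray(predictors, float)})
    if not 1 <= frame.shape[1] <= 2:
        raise ValueError("expected one or two predictors")
    return frame.astype(float)


def _complete_cases(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    return ~(np.isnan(y) | np.isnan(X).any(axis=1))


def fit_linear(response, predictors) -> ModelFit:
    """Ordinary least squares of the response on one or two predictors.

    Missing values are dropped casewise.  Raises on collinear predictors or
    on fewer complete cases than coefficients + 2.
    """
    frame = _as_predictor_frame(predictors)
    names = tuple(frame.columns)
    y = np.asarray(response, float)
    X = frame.to_numpy()
    mask = _complete_cases(y, X)
    y, X = y[mask], X[mask]
    n, k = X.shape
    p = k + 1
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {n}")
    design = sm.add_constant(X)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("predictors are collinear")
    fit = sm.OLS(y, design).fit()
    coefs = {_COEF_NAMES[i]: float(b) for i, b in enumerate(fit.params)}
    ses = {_COEF_NAMES[i]: float(s) for i, s in enumerate(fit.bse)}
    return ModelFit(
        family="linear", coefficients=coefs, se=ses, predictor_names=names,
        rmse=float(np.sqrt(fit.mse_resid)), r2=float(fit.rsquared),
        p_model=float(fit.f_pvalue), n=int(n), sse=float(fit.ssr),
    )


def fit_exponential(
    response,
    predictors,
    *,
    rel_tol: float = 1e-10,
    max_iter: int = 200,
) -> ModelFit:
    """Least-squares exponential fit y = C1*exp(C2*x1 [+ C3*x2]).

    Minimizes the SSE on the original (untransformed) scale.  Starting
    values come from OLS on log(y); Gauss-Newton steps with halving then
    refine them, so the final SSE never exceeds the initializer's.
    Deterministic given the data (no random restarts).

    Raises
    ------
    ConvergenceError
        If the relative SSE change has not dropped below ``rel_tol``
        within ``max_iter`` iterations.
    """
    frame = _as_predictor_frame(predictors)
    names = tuple(frame.columns)
    y = np.asarray(response, float)
    X = frame.to_numpy()
    mask = _complete_cases(y, X)
    y, X = y[mask], X[mask]
    n, k = X.shape
    p = k + 1
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} complete cases, got {n}")
    pos = y > 0
    if pos.sum() < p + 2:
        raise ValueError(
            "need a strictly positive response on at least p + 2 cases for "
            "the log-linear initialization"
        )
    init = sm.OLS(np.log(y[pos]), sm.add_constant(X[pos], has_constant="add")).fit().params
    theta = np.concatenate([[math.exp(init[0])], init[1:]])

    def model(th: np.ndarray) -> np.ndarray:
        return th[0] * np.exp(X @ th[1:])

    def sse_of(th: np.ndarray) -> float:
        r = y - model(th)
        return float(r @ r)

    trace = [sse_of(theta)]
    converged = False
    for _ in range(max_iter):
        mu = model(theta)
        resid = y - mu
        # Jacobian of mu wrt (C1, C2[, C3])
        J = np.column_stack([mu / theta[0]] + [mu * X[:, j] for j in range(k)])
        step, *_ = np.linalg.lstsq(J, resid, rcond=None)
        t, new_sse = 1.0, None
        for _half in range(60):
            cand = theta + t * step
            s = sse_of(cand)
            if s < trace[-1] or math.isclose(s, trace[-1], rel_tol=1e-15):
                new_sse = s
                theta = cand
                break
            t *= 0.5
        if new_sse is None:  # no descent direction left: at a local optimum
            converged = True
            break
        trace.append(new_sse)
        denom = max(trace[-2], np.finfo(float).tiny)
        if abs(trace[-2] - trace[-1]) / denom < rel_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"exponential fit did not converge in {max_iter} iterations",
            theta, trace,
        )

    sse = sse_of(theta)
    mu = model(theta)
    J = np.column_stack([mu / theta[0]] + [mu * X[:, j] for j in range(k)])
    s2 = sse / (n - p)
    cov = s2 * np.linalg.inv(J.T @ J)
    ses = np.sqrt(np.diag(cov))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    if s2 > 0 and sst > 0:
        f = ((sst - sse) / (p - 1)) / s2
        p_model = float(stats.f.sf(f, p - 1, n - p))
    else:
        p_model = 0.0 if sst > sse else float("nan")  # perfect fit
    return ModelFit(
        family="exponential",
        coefficients={_COEF_NAMES[i]: float(b) for i, b in enumerate(theta)},
        se={_COEF_NAMES[i]: float(s) for i, s in enumerate(ses)},
        predictor_names=names,
        rmse=float(np.sqrt(s2)), r2=float(r2), p_model=p_model,
        n=int(n), sse=sse,
    )


@dataclass
class BrokenLineFit:
    """One-slope broken-line fit y = L + U*max(R - x, 0).

    ``plateau`` (L) is the response level beyond the breakpoint ``R``;
    ``slope`` (U) is the rate of change per kg below it.  With
    ``orientation='increasing'`` the mirrored form L + U*max(x - R, 0) is
    fitted instead.  ``degenerate`` flags a breakpoint pinned at the data
    boundary (no curvature detected); standard errors for L and U are
    conditional on the estimated breakpoint.
    """

    plateau: float
    slope: float
    breakpoint: float
    se_plateau: float
    se_slope: float
    se_breakpoint: float
    rmse: float
    r2: float
    p_model: float
    n: int
    sse: float
    orientation: str = "decreasing"
    degenerate: bool = False
    family: str = field(default="broken_line", init=False)

    @property
    def n_coefficients(self) -> int:
        return 3

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.orientation == "decreasing":
            hinge = np.maximum(self.breakpoint - x, 0.0)
        else:
            hinge = np.maximum(x - self.breakpoint, 0.0)
        return self.plateau + self.slope * hinge

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": {"plateau": self.plateau, "slope": self.slope,
                             "breakpoint": self.breakpoint},
            "se": {"plateau": self.se_plateau, "slope": self.se_slope,
               "breakpoint": self.se_breakpoint},
            "rmse": self.rmse, "r2": self.r2, "p_model": self.p_model,
            "n": self.n, "orientation": self.orientation,
            "degenerate": self.degenerate,
        }


def _profile_sse(xs: np.ndarray, ys: np.ndarray, R: np.ndarray) -> np.ndarray:
    """SSE of the hinge regression y ~ 1 + max(R - x, 0), vectorized over R.

    ``xs``/``ys`` must be sorted by x.  Uses prefix sums: for a candidate R,
    only points with x < R contribute a nonzero hinge, so all the OLS
    cross-products are O(1) per candidate after an O(n) pass.
    """
    n = xs.size
    px = np.concatenate([[0.0], np.cumsum(xs)])
    px2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
    py = np.concatenate([[0.0], np.cumsum(ys)])
    pxy = np.concatenate([[0.0], np.cumsum(xs * ys)])
    sy, syy = ys.sum(), float(ys @ ys)
    Syy = syy - sy * sy / n

    j = np.searchsorted(xs, R, side="left")  # count of x strictly below R
    sh = j * R - px[j]
    sh2 = j * R * R - 2.0 * R * px[j] + px2[j]
    shy = R * py[j] - pxy[j]
    Shh = sh2 - sh * sh / n
    Shy = shy - sh * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = Syy - np.where(Shh > 1e-12 * max(sh2.max(initial=1.0), 1.0),
                             Shy * Shy / Shh, 0.0)
    return np.maximum(sse, 0.0)


def _interior_candidates(xs: np.ndarray, ys: np.ndarray, uniq: np.ndarray) -> np.ndarray:
    """Stationary breakpoints of the profile SSE inside each interval
    between consecutive distinct x values, in closed form.

    With the active set {x < R} fixed, the centered cross-products are
    polynomials in R — Shy(R) = alpha*R + beta and Shh(R) = a*R^2 + b*R + c
    — and the profile SSE is Syy - Shy^2/Shh.  Its nontrivial stationary
    condition reduces to the linear equation (alpha*b - 2*a*beta)*R =
    beta*b - 2*alpha*c, giving at most one interior candidate per interval.
    """
    n = xs.size
    px = np.concatenate([[0.0], np.cumsum(xs)])
    px2 = np.concatenate([[0.0], np.cumsum(xs * xs)])
    py = np.concatenate([[0.0], np.cumsum(ys)])
    pxy = np.concatenate([[0.0], np.cumsum(xs * ys)])
    sy = ys.sum()

    lo_edge, hi_edge = uniq[:-1], uniq[1:]
    j = np.searchsorted(xs, lo_edge, side="right")  # active count on (lo, hi]
    P1, P2, Py, Pxy = px[j], px2[j], py[j], pxy[j]
    alpha = Py - j * sy / n
    beta = P1 * sy / n - Pxy
    a = j * (1.0 - j / n)
    b = -2.0 * P1 * (1.0 - j / n)
    c = P2 - P1 * P1 / n
    denom = alpha * b - 2.0 * a * beta
    with np.errstate(divide="ignore", invalid="ignore"):
        r_star = (beta * b - 2.0 * alpha * c) / denom
    ok = np.isfinite(r_star) & (r_star > lo_edge) & (r_star < hi_edge)
    return r_star[ok]


def fit_broken_line(response, x, orientation: str = "decreasing") -> BrokenLineFit:
    """Fit the one-slope broken-line model by profiling the breakpoint.

    For each candidate breakpoint the model is linear in (plateau, slope)
    and solved by OLS on the hinge covariate; candidates are all observed
    x values above the minimum together with the closed-form stationary
    point of the profile SSE inside every interval between consecutive
    observed values, so the profiled minimum is exact.

    Requires n >= 5 complete cases and at least 3 distinct x values.
    """
    if orientation not in ("decreasing", "increasing"):
        raise ValueError("orientation must be 'decreasing' or 'increasing'")
    y = np.asarray(response, float)
    xv = np.asarray(x, float)
    mask = ~(np.isnan(y) | np.isnan(xv))
    y, xv = y[mask], xv[mask]
    n = y.size
    if n < 5:
        raise ValueError(f"need at least 5 complete cases, got {n}")
    if np.unique(xv).size < 3:
        raise ValueError("x must have at least 3 distinct values")

    # mirrored form reduces to the canonical one on reflected x
    sign = 1.0 if orientation == "decreasing" else -1.0
    xw = sign * xv
    order = np.argsort(xw, kind="stable")
    xs, ys = xw[order], y[order]

    uniq = np.unique(xs)
    boundary = uniq[1:]  # R = min(x) gives an all-zero hinge
    candidates = np.concatenate([boundary, _interior_candidates(xs, ys, uniq)])
    sse_all = _profile_sse(xs, ys, candidates)
    best = int(np.argmin(sse_all))
    R = float(candidates[best])

    hinge = np.maximum(R - xs, 0.0)
    design = sm.add_constant(hinge, has_constant="add")
    ols = sm.OLS(ys, design).fit()
    L, U = float(ols.params[0]), float(ols.params[1])
    sse = float(ols.ssr)

    p = 3
    s2 = sse / (n - p)
    # nonlinear-LS covariance from the full Jacobian in (L, U, R);
    # d(yhat)/dR = U on the sloped segment, 0 on the plateau
    J = np.column_stack([np.ones(n), hinge, np.where(xs < R, U, 0.0)])
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_L, se_U, se_R = (float(np.sqrt(cov[i, i])) for i in range(3))
    except np.linalg.LinAlgError:
        # flat or boundary fit: fall back to the breakpoint-conditional form
        cov2 = s2 * np.linalg.inv(design.T @ design)
        se_L, se_U = float(np.sqrt(cov2[0, 0])), float(np.sqrt(cov2[1, 1]))
        se_R = float("nan")
    sst = float(np.sum((ys - ys.mean()) ** 2))
    degenerate = False
    if sst <= 0:
        r2, p_model = float("nan"), float("nan")
        degenerate = True
    else:
        r2 = 1.0 - sse / sst
        f = ((sst - sse) / (p - 1)) / s2 if s2 > 0 else float("inf")
        p_model = float(stats.f.sf(f, p - 1, n - p))
    if R >= xs[-1] or R <= xs[0]:
        degenerate = True

    return BrokenLineFit(
        plateau=L, slope=U, breakpoint=sign * R,
        se_plateau=se_L, se_slope=se_U, se_breakpoint=se_R,
        rmse=float(np.sqrt(s2)), r2=r2, p_model=p_model,
        n=int(n), sse=sse, orientation=orientation, degenerate=degenerate,
    )


@dataclass(frozen=True)
class AAEquation:
    """Simple linear equation: BEL of one amino acid from BEL of CP."""

    aa: str
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    rmse: float
    r2: float
    p_model: float
    n: int

    def predict(self, bel_cp) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(bel_cp, float)


def fit_aa_equations(dataset: Dataset, min_n: int = 4) -> list[AAEquation]:
    """One linear fit per amino acid, with BEL of CP as the predictor.

    Amino acids with fewer than ``min_n`` complete (bel_cp, bel_aa) pairs
    are skipped with a logged notice.
    """
    cp = dataset.column("bel_cp")
    out = []
    for aa in AA_CODES:
        yv = dataset.column(aa)
        n_pairs = int(np.sum(~np.isnan(cp) & ~np.isnan(yv)))
        if n_pairs < min_n:
            logger.info("skipping %s: only %d complete (bel_cp, %s) pairs",
                        aa, n_pairs, aa)
            continue
        fit = fit_linear(yv, {"bel_cp": cp})
        out.append(AAEquation(
            aa=aa,
            intercept=fit.coefficients["C1"], slope=fit.coefficients["C2"],
            se_intercept=fit.se["C1"], se_slope=fit.se["C2"],
            rmse=fit.rmse, r2=fit.r2, p_model=fit.p_model, n=fit.n,
        ))
    return out


def compare_models(fits) -> list:
    """Rank fits by ascending RMSE; ties by descending R^2, then fewer
    coefficients (parsimony)."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    return sorted(fits, key=lambda f: (f.rmse, -f.r2, f.n_coefficients))


def ranking_frame(fits) -> pd.DataFrame:
    """Ranked comparison as a DataFrame."""
    ranked = compare_models(fits)
    rows = []
    for rank, f in enumerate(ranked, start=1):
        rows.append({
            "rank": rank, "family": f.family, "rmse": f.rmse, "r2": f.r2,
            "p_model": f.p_model, "n_coefficients": f.n_coefficients, "n": f.n,
        })
    return pd.DataFrame(rows)
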