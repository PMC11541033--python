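"""Synthetic observation tables with the structure the analysis assumes.

No literature dataset ships with the package, so every pipeline stage is
exercised on generated data that emulates the published summary structure:
initial body weight from a truncated normal over the observed range,
feeding level (FI:MFI) truncated at the 3.0 cap, BEL of crude protein from
a broken-line truth in body weight (declining to a plateau at 62 kg) with
residual noise at the published scatter, and each amino acid generated
conditionally on CP from its published linear equation with residual SD
equal to that equation's RMSE.  Feed intake is back-computed from FI:MFI
so that the preprocessing derivation round-trips exactly.

Truths are swappable: linear and exponential CP truths support parameter-
recovery studies for those fitters.  Missingness and gross-outlier
injection are configurable; defaults emulate the published per-variable
availability pattern.

Determinism: a single generator stream drawn strictly row by row, so row k
is reproducible regardless of how many rows follow it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .core_data import AA_CODES, Dataset, Observation
from .preprocessing import MaintenanceModel, maintenance_me
from .prediction import default_registry


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal distribution truncated to [lower, upper] by rejection.

    ``mean`` and ``sd`` are the location and scale of the underlying
    (untruncated) normal; the truncated distribution's own moments differ
    whenever a bound cuts into the density.  Use :meth:`from_moments` to
    target the moments of the truncated distribution instead.
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.lower < self.upper:
            raise ValueError("bounds must be ordered")

    @classmethod
    def from_moments(cls, mean: float, sd: float,
                     lower: float, upper: float) -> "TruncatedNormal":
        """Truncated normal whose post-truncation mean and SD equal the
        targets, found by solving for the underlying location and scale."""
        from scipy import optimize, stats

        def residuals(params):
            loc, log_scale = params
            scale = math.exp(log_scale)
            a, b = (lower - loc) / scale, (upper - loc) / scale
            m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale,
                                         moments="mv")
            return [float(m) - mean, math.sqrt(float(v)) - sd]

        sol, info, ok, _ = optimize.fsolve(
            residuals, [mean, math.log(sd)], full_output=True)
        if ok != 1 or max(abs(r) for r in residuals(sol)) > 1e-8:
            raise ValueError(
                f"no truncated normal on [{lower}, {upper}] attains "
                f"mean {mean}, sd {sd}")
        return cls(float(sol[0]), math.exp(float(sol[1])), lower, upper)

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(10000):
            v = rng.normal(self.mean, self.sd)
            if self.lower <= v <= self.upper:
                return v
        raise RuntimeError("rejection sampling failed; bounds too narrow")

    def draw_many(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Vectorized rejection draw of n values."""
        if self.sd == 0:
            return np.full(n, self.mean)
        out = np.empty(n)
        todo = np.arange(n)
        while todo.size:
            v = rng.normal(self.mean, self.sd, todo.size)
            ok = (v >= self.lower) & (v <= self.upper)
            out[todo[ok]] = v[ok]
            todo = todo[~ok]
        return out


@dataclass(frozen=True)
class BrokenLineTruth:
    """CP truth: plateau + slope * max(breakpoint - ibw, 0) + noise."""

    plateau: float = 14.78
    slope: float = 0.102
    breakpoint: float = 62.0
    residual_sd: float = 4.89
    bounds: tuple[float, float] | None = (6.1, 29.1)

    def mean(self, ibw):
        return self.plateau + self.slope * np.maximum(self.breakpoint - np.asarray(ibw, float), 0.0)


@dataclass(frozen=True)
class LinearTruth:
    """CP truth: intercept + slope * ibw + noise."""

    intercept: float = 20.36
    slope: float = -0.077
    residual_sd: float = 4.87
    bounds: tuple[float, float] | None = None

    def mean(self, ibw):
        return self.intercept + self.slope * np.asarray(ibw, float)


@dataclass(frozen=True)
class ExponentialTruth:
    """CP truth: scale * exp(rate * ibw) + noise."""

    scale: float = 20.80
    rate: float = -0.00475
    residual_sd: float = 4.86
    bounds: tuple[float, float] | None = None

    def mean(self, ibw):
        return self.scale * np.exp(self.rate * np.asarray(ibw, float))


@dataclass(frozen=True)
class AATruth:
    """Amino-acid truth conditional on CP: intercept + slope * cp + noise >= 0."""

    intercept: float
    slope: float
    residual_sd: float

    def mean(self, bel_cp):
        return self.intercept + self.slope * np.asarray(bel_cp, float)


def published_aa_truths() -> dict[str, AATruth]:
    """Per-AA truths from the published equations (residual SD = RMSE)."""
    reg = default_registry()
    return {
        aa: AATruth(eq["intercept"], eq["slope"], eq["rmse"])
        for aa, eq in reg.aa_equations.items()
    }


#: Body-weight distribution calibrated so the truncated draws themselves
#: have mean 43.2 kg and SD 22.2 kg over the observed range [9.2, 109.8].
DEFAULT_IBW_DIST = TruncatedNormal.from_moments(43.2, 22.2, 9.2, 109.8)

#: Feeding level: nominal mean 2.73 and SD 0.27, truncated to [1.0, 3.0].
#: (No truncated normal attains those moments after truncation at 3.0 —
#: that corner is the one-sided exponential limit — so the nominal values
#: parameterize the underlying normal.)
DEFAULT_FIMFI_DIST = TruncatedNormal(2.73, 0.27, 1.0, 3.0)

#: Per-variable missing probabilities emulating the published availability
#: counts out of 139 observations (e.g. CP reported for 117 of 139).
DEFAULT_MISSINGNESS: dict[str, float] = {
    "bel_cp": 22 / 139,
    "met": 1 / 139, "thr": 1 / 139, "val": 1 / 139,
    "trp": 11 / 139,
    "ala": 2 / 139, "asp": 4 / 139, "cys": 7 / 139,
    "glu": 5 / 139, "gly": 5 / 139,
    "pro": 24 / 139, "ser": 4 / 139, "tyr": 33 / 139,
}


@dataclass(frozen=True)
class OutlierInjection:
    """Gross-outlier spec: ``count`` rows get high-leverage body weights and
    a CP offset of ``offset_sds`` residual standard deviations."""

    count: int = 0
    offset_sds: float = 8.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    n: int = 139
    seed: int = 0
    ibw_dist: TruncatedNormal = DEFAULT_IBW_DIST
    diet_me_dist: TruncatedNormal = TruncatedNormal(3900.0, 150.0, 500.0)
    fimfi_dist: TruncatedNormal = DEFAULT_FIMFI_DIST
    cp_truth: BrokenLineTruth | LinearTruth | ExponentialTruth = BrokenLineTruth()
    aa_truths: Mapping[str, AATruth] = field(default_factory=published_aa_truths)
    missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    outliers: OutlierInjection = OutlierInjection(0)
    maintenance: MaintenanceModel = MaintenanceModel()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.cp_truth.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for var, prob in self.missingness.items():
            if not 0 <= prob <= 1:
                raise ValueError(f"missingness[{var!r}] must lie in [0, 1]")


def _draw_cp(rng: np.random.Generator, truth, ibw: float) -> float:
    mu = float(truth.mean(ibw))
    if truth.bounds is None:
        return mu + rng.normal(0.0, truth.residual_sd)
    lo, hi = truth.bounds
    return TruncatedNormal(mu, truth.residual_sd, lo, hi).draw(rng)


def _draw_aa(rng: np.random.Generator, truth: AATruth, cp: float) -> float:
    mu = float(truth.mean(cp))
    for _ in range(10000):
        v = mu + rng.normal(0.0, truth.residual_sd)
        if v >= 0:
            return v
    return 0.0  # deeply negative mean: pin at the physical floor


def generate(config: GeneratorConfig) -> Dataset:
    """Generate a synthetic Dataset.  Fully deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n_outliers = min(config.outliers.count, config.n)
    observations: list[Observation] = []
    for k in range(config.n):
        is_outlier = k >= config.n - n_outliers
        ibw = config.ibw_dist.draw(rng)
        fi_mfi = config.fimfi_dist.draw(rng)
        diet_me = config.diet_me_dist.draw(rng)
        feed_intake = fi_mfi * maintenance_me(ibw, config.maintenance) / diet_me
        cp = _draw_cp(rng, config.cp_truth, ibw)
        aas = {aa: _draw_aa(rng, truth, cp)
               for aa, truth in config.aa_truths.items()}

        # missingness draws happen for every row in a fixed variable order
        # so the stream position stays reproducible
        missing = {var: rng.random() < prob
                   for var, prob in sorted(config.missingness.items())}

        if is_outlier:
            # high-leverage body weight with a gross CP offset; exempt from
            # missingness so the screen can always see it
            hi = config.ibw_dist.upper
            ibw = hi - 0.02 * (hi - config.ibw_dist.lower) * rng.random()
            feed_intake = fi_mfi * maintenance_me(ibw, config.maintenance) / diet_me
            cp = float(config.cp_truth.mean(ibw)) + \
                config.outliers.offset_sds * config.cp_truth.residual_sd
            missing["bel_cp"] = False

        obs = Observation(
            study_id=f"outlier{k}" if is_outlier else f"synth{k}",
            ibw=ibw, feed_intake=feed_intake, diet_me=diet_me,
            fi_mfi=fi_mfi,
            bel_cp=None if missing.get("bel_cp") else cp,
            bel_aa={aa: v for aa, v in aas.items()
                    if not missing.get(aa.lower())},
        )
        observations.append(obs)
    return Dataset(observations, [
        f"synthetic: n={config.n}, seed={config.seed}, "
        f"cp_truth={type(config.cp_truth).__name__}, "
        f"outliers={n_outliers}"
    ])


def generate_validation_pair(
    config: GeneratorConfig,
    equation: Callable,
) -> tuple[np.ndarray, np.ndarray]:
    """Row-aligned (measured, predicted) BEL-of-CP vectors.

    ``equation`` takes (ibw) or (ibw, fi_mfi) and returns predicted BEL of
    CP.  Rows without a measured value are dropped.
    """
    import inspect

    dataset = generate(config)
    try:
        n_params = len(inspect.signature(equation).parameters)
    except (TypeError, ValueError):
        n_params = 2
    measured, predicted = [], []
    for obs in dataset:
        if obs.bel_cp is None:
            continue
        args = (obs.ibw,) if n_params == 1 else (obs.ibw, obs.fi_mfi)
        measured.append(obs.bel_cp)
        predicted.append(float(equation(*args)))
    return np.array(measured), np.array(predicted)


def sample_cp_observations(
    truth,
    n: int,
    rng: np.random.Generator | int,
    ibw_dist: TruncatedNormal = DEFAULT_IBW_DIST,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ibw, bel_cp) sample from one CP truth.

    Intended for parameter-recovery studies, where only the regression
    pair is needed and the full observation table would be wasteful.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ibw = ibw_dist.draw_many(rng, n)
    y = np.asarray(truth.mean(ibw), float) + rng.normal(0.0, truth.residual_sd, n)
    if truth.bounds is not None:
        lo, hi = truth.bounds
        todo = np.flatnonzero((y < lo) | (y > hi))
        mu = np.asarray(truth.mean(ibw), float)
        while todo.size:
            y[todo] = mu[todo] + rng.normal(0.0, truth.residual_sd, todo.size)
            ok = (y[todo] >= lo) & (y[todo] <= hi)
            todo = todo[~ok]
    return ibw, y


def sample_aa_observations(
    truth: AATruth,
    bel_cp: np.ndarray,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Vectorized amino-acid sample conditional on given CP values."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    cp = np.asarray(bel_cp, float)
    y = np.asarray(truth.mean(cp), float) + rng.normal(0.0, truth.residual_sd, cp.size)
    mu = np.asarray(truth.mean(cp), float)
    todo = np.flatnonzero(y < 0)
    for _ in range(1000):
        if not todo.size:
            break
        y[todo] = mu[todo] + rng.normal(0.0, truth.residual_sd, todo.size)
        todo = todo[y[todo] < 0]
    else:
        y[todo] = 0.0  # deeply negative mean: pin at the physical floor
    return y
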