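# Methods

## The quantity being modelled

Basal endogenous losses (BEL) are the crude protein (CP) and amino acids
(AA) arriving at the terminal ileum that do not originate from the diet —
mucins, sloughed cells, enzyme residues.  They are expressed per unit of
intake (g/kg DMI) because they are the correction term that turns apparent
ileal digestibility into standardized ileal digestibility.  Measured
values come from pigs fed nitrogen-free diets, so every gram of ileal
CP/AA flow is endogenous by construction.

The pipeline models two relationships observed in pooled literature data:

1. BEL of CP falls with body weight in young pigs and levels off in
   finishing pigs, described by three interchangeable families — linear,
   exponential decay, and a one-slope broken line with a plateau;
2. BEL of each amino acid is, to a good approximation, proportional to
   BEL of CP (endogenous protein has a fairly stable AA composition, with
   proline and glycine as high-variance outliers tied to body-protein
   mobilization), so each AA gets a simple linear equation in BEL of CP.

All models pool observations across studies; there are no study-level
random effects (the source tables report pooled regressions, and no
between-study variance component is recoverable from them).

## Preprocessing: feeding level

Feeding level enters as FI:MFI — feed intake as a multiple of maintenance
feed intake.  Maintenance feed intake is the maintenance ME requirement,
`coefficient × BW^exponent` (defaults 197 kcal/d·kg^-0.60 and 0.60,
the NRC metabolic-body-weight form), divided by the diet ME concentration
(kcal/kg DM).  A reported FI:MFI always wins over a derived one.  Values
above the expected voluntary intake of crossbred pigs are capped; the
default policy is the constant ceiling 3.0 (the only cap value the source
data support — their observed maximum), with an injectable BW→intake
lookup for users who want weight-specific NRC ceilings.

## Outlier screen

A single pass of Cook's distance on an OLS screening model (default:
BEL of CP on IBW), removing points with D strictly greater than Fox's
criterion 4/(n − k − 1), k counting predictors without the intercept
(4/153 ≈ 0.026 at n = 155, k = 1).  Ties at the threshold are kept.  The
pass is not iterated: re-screening the survivors would remove more points
and has no support in the procedure being reproduced.  Rows missing a
screening variable cannot be scored and pass through, listed separately.

## Model fitting

* **Linear** models are OLS (statsmodels), with SEs from the unbiased
  residual variance, RMSE = sqrt(SSE/(n − p)), and the overall-F p-value.
* **Exponential** models minimize SSE on the original scale.  Start
  values come from OLS on log(y) (computed on the positive responses;
  synthetic data at realistic noise can dip below zero even though
  measured BEL cannot), refined by Gauss–Newton with step halving.
  Convergence: relative SSE change < 1e-10, at most 200 iterations,
  otherwise an error carrying the SSE trace.  No random restarts: the fit
  is a deterministic function of the data.  R² is 1 − SSE/SST about the
  response mean (the NLIN-style convention; it can be negative), and the
  reported p-value is the F test against the intercept-only model.
* **One-slope broken line** `y = L + U·max(R − x, 0)`: for fixed R the
  model is linear in (L, U), so R is profiled out.  Between consecutive
  distinct x values the active set {x < R} is constant and the profile
  SSE is `Syy − Shy(R)²/Shh(R)` with Shy linear and Shh quadratic in R;
  its nontrivial stationary condition reduces to one linear equation per
  interval.  The minimizer is therefore found exactly by evaluating every
  observed x (above the minimum) plus every interior stationary point,
  all in O(n log n) via prefix sums — no iterative refinement and no
  tolerance beyond float arithmetic.  An earlier design refined only
  around the best observed candidate (golden section); it was replaced
  because the profile SSE is multimodal across intervals and a dense-grid
  oracle found lower SSE on random instances.  Standard errors come from
  the nonlinear-LS Jacobian in (L, U, R) (the R column is U on the sloped
  segment, 0 on the plateau); when that matrix is singular — flat data or
  a boundary breakpoint — the fit falls back to breakpoint-conditional
  SEs and is flagged degenerate rather than erroring.  Default
  orientation is decreasing-then-plateau (the biology: losses per kg DMI
  fall to ~62 kg and then stay constant); a mirrored form is available.
* **Model comparison** ranks by ascending RMSE, then descending R², then
  fewer coefficients.

## Validation regression

A candidate CP equation is evaluated by OLS of (measured − predicted) on
(predicted − mean predicted).  The intercept is the mean bias (average
offset, g/kg DMI) and the slope the linear bias (proportional misfit);
both get two-sided t tests on n − 2 df.  Evaluating an OLS fit on its own
training data returns biases that are numerically zero — a normal-
equations identity the tests assert at 1e-10.  Constant predictions are
rejected (the slope is undefined).  The equation being validated is
caller-supplied; no prior equation's coefficients are built in.

## Prediction API

The published equations live in a checked-in JSON constants file and are
exposed by model name.  Negative AA predictions (possible below the
x-intercept of the Pro, Gly and Arg equations) are clipped to zero with a
flag — endogenous losses cannot be negative, and erroring would make the
profile function unusable at low CP.  Body weights outside the observed
range [9.2, 109.8] kg warn but proceed; extrapolating to a 5-kg weanling
is a legitimate, if risky, use.

## Synthetic data

The generator emulates the *structure* the analysis assumes, not any real
dataset: IBW from a truncated normal over [9.2, 109.8] kg whose
post-truncation mean and SD are calibrated to 43.2 and 22.2 kg (the
underlying location/scale are solved numerically; naive truncation of
N(43.2, 22.2²) would inflate the realized mean by ≈ 2.8 kg); FI:MFI from
a truncated normal with nominal mean 2.73 and SD 0.27 on [1.0, 3.0]
(those post-truncation moments sit exactly on the one-sided exponential
limit of the truncated-normal family and are not attainable, so the
nominal values parameterize the underlying normal); diet ME normal around
3,900 kcal/kg DM (SD 150) — no ME concentration is published, and this
value is consistent with the reported mean daily ME intake at the mean
intake and is config-overridable; feed intake back-computed as
FI:MFI × ME_m/diet ME so preprocessing round-trips exactly; BEL of CP
from the broken-line truth (14.78, 0.102, 62.0) with residual SD 4.89
truncated to the observed range [6.1, 29.1]; each AA conditionally on CP
from its published equation with residual SD equal to that equation's
RMSE, truncated at zero.  Default per-variable missingness mirrors the
published availability counts (e.g. CP present for 117 of 139 rows).
Draws are strictly sequential from one seeded stream, so row k is
identical whatever the total n.  Linear and exponential CP truths (with
optional unbounded noise) support parameter-recovery studies.

Not emulated: between-study heterogeneity (no variance estimate exists to
calibrate it), correlated missingness, measurement-method effects, or any
skewness in the real residuals.  Passing recovery tests therefore show
the estimators work under the assumed data-generating process, not that
the published equations are correct for real pigs.

Problem sizes used in the shipped tests — n = 5,000 with 50–100 seeded
replicates for recovery suites, one n = 50,000 draw for moment checks —
were chosen as the smallest sizes at which the stochastic tolerances are
comfortably resolved.

## Known limitations

* **Screening a curved relationship distorts it.**  Cook's distance is
  computed against a straight-line screening model; on broken-line data
  the misfit concentrates at extreme body weights, exactly where leverage
  is highest, so the screen preferentially removes informative extreme
  points.  Measured at n = 5,000 under the default truth this shifts the
  estimated breakpoint by ≈ +6.5 kg regardless of sample size (both the
  threshold and per-point influence scale as 1/n, so the flagged fraction
  is scale-invariant).  The pipeline reproduces the screening procedure
  faithfully; users fitting the broken line should be aware the screen is
  not innocuous, and the recovery guarantees in the tests are stated for
  the unscreened fit.
* The FI:MFI marginal distribution cannot match all published moments
  (see above); its realized mean is ≈ 2.66 rather than 2.73.
* The AA-on-CP generation direction induces the qualitative sign pattern
  of the published correlation table but not its magnitudes; only signs
  are asserted.
* Degenerate broken-line fits (no curvature in the data) return flagged
  estimates with breakpoint-conditional SEs; the breakpoint SE is NaN in
  that case.
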