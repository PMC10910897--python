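# Methods

## Models

All five families are ordinary least-squares fits of the form
y = Xβ + ε with i.i.d. Gaussian errors; they differ only in the design
matrix X built from the exposure x:

| family        | columns beyond the intercept                         | p |
|---------------|------------------------------------------------------|---|
| linear        | x                                                    | 1 |
| quadratic     | x, x²                                                | 2 |
| categorical   | I(q₁<x≤q₂), I(q₂<x≤q₃), I(x>q₃) (quartile dummies)   | 3 |
| lsp (K knots) | x, (x−k₁)₊, …, (x−k_K)₊                              | K+1 |
| rcs (3 knots) | x, s(x) (normalised restricted-cubic column)         | 2 |

Truncated power terms use the convention (x−k)₊ = 0 whenever x ≤ k, so
every lower interval includes its right boundary; quartile categorization
uses the same left-open/right-closed cuts for consistency.

The restricted cubic basis is

s(x) = [(x−k₁)₊³ − (x−k₂)₊³ (k₃−k₁)/(k₃−k₂) + (x−k₃)₊³ (k₂−k₁)/(k₃−k₂)] / (k₃−k₁)²

The two inner weights are the unique combination that cancels both the
cubic and quadratic terms beyond k₃, making the curve linear in both tails
and C² everywhere. The (k₃−k₁)² divisor is a pure normalisation keeping
the spline coefficient on a scale comparable to the linear slope; the
conversion to per-interval truncated-cubic coefficients
(β₂* = β/(k₃−k₁)², β₃* = β₂*(k₁−k₃)/(k₃−k₂), β₄* = β₂*(k₁−k₂)/(k₂−k₃))
is then an exact identity, verified in-suite to 1e-10 on dense grids.
Only the 3-knot restricted basis is implemented; higher knot counts and
B-spline parameterisations are out of scope for this toolkit.

A caution that the test suite makes explicit: the converted coefficients
live on the 1e-7 scale for mm-scale exposures, and evaluating the interval
form with coefficients rounded to 7 decimals changes one-unit contrasts in
the third decimal (cancellation between large cubic terms amplifies the
rounding). The toolkit computes full-precision conversions; reproductions
of published arithmetic that used rounded coefficients must round first,
which is what the acceptance script does.

## Knot placement

Knots default to fixed percentiles of the observed exposure (50 for one
knot; 10/50/90 for three; 5/35/65/95 for four; 5/27.5/50/72.5/95 for five
— the last is a toolkit default extending the same scheme). Quantiles are
computed by linear interpolation of order statistics ("type 7", numpy's
default); the rule name is recorded in report metadata because published
knot values obtained under another convention will differ slightly. Ties
that collapse two requested knots raise an error rather than silently
merging, since spline bases require distinct knots. Data-driven selection
of the knot count is deliberately not provided.

## Estimation and inference

The solver scales each design column to unit Euclidean norm, solves by QR
(numpy `lstsq`), applies one step of iterative refinement, and rescales —
necessary because truncated-cubic columns reach ~1e9 on mm-scale data.
Normal equations are never formed. The test suite checks coefficients
against an exact rational-arithmetic solver (floats are dyadic rationals,
so the Gram system can be solved without rounding) to 1e-8 relative error,
and against statsmodels OLS as an independent library cross-check.

Fit statistics: r² = 1 − SSE/SST (defined as 0 for a constant outcome) and
adjusted r² = 1 − (1−r²)(n−1)/(n−p−1), with p counted from the fitted
design (3 dummies for categorization, 2 for the 3-knot RCS). Wald
confidence intervals use t quantiles with n−p−1 degrees of freedom — the
t/normal choice is a genuinely open convention; t is slightly conservative
and consistent with the OLS variance estimate. Interval slopes and
exposure contrasts are linear combinations c'β, so their standard errors
come from c'Σc with the same t quantiles.

The bootstrap (default B = 1000, percentile method, seeded and
deterministic) resamples cases with knots and quartile bounds held fixed
at their original-sample values, mirroring a pre-specified-knot workflow.
This understates the variability that re-estimating knots per resample
would add — a documented limitation, not an oversight. Resamples with a
singular design (e.g. an empty quartile) are redrawn, capped at 100 with a
warning.

## Synthetic-data generator

The generator emulates the motivating example — sum of four skinfolds
(mm) against maximal oxygen uptake (cl/kg) in 315 adolescents:

- **Exposure**: log-normal, mu = 5.8626, sigma = 0.4196 (log-mm). These
  are the least-squares solution in log space to placing the 10th/50th/90th
  percentiles at 212/330/621.4 mm, the example's knot locations. A
  log-normal cannot hit all three exactly (they are not log-symmetric);
  the defaults land near 205/352/601 mm, spanning roughly 110–1,300 mm.
- **Truth**: by default the continuous piecewise-linear curve with those
  knots, intercept 64.1788 cl/kg and interval slopes
  (−0.0156, −0.0827, −0.0226, −0.0098) cl/kg per mm — the example's 3-knot
  linear-spline fit. A smooth restricted-cubic truth is also available to
  exercise misspecification behaviour.
- **Noise**: additive i.i.d. Gaussian. The default sd (≈ 4.74 cl/kg) is
  solved analytically so the population explained variance
  var f(X) / (var f(X) + sd²) equals 0.582, the example's 3-knot LSP
  adjusted r². The moments of f(X) are computed by adaptive quadrature
  against the log-normal density with the knots as breakpoints, so the
  target is hit to ~1e-9 and fitted adjusted r² has an analytic value to
  converge to.

What the generator does **not** emulate: covariates or confounders,
missingness (the example excluded 6 incomplete cases, mechanism unknown),
heteroscedasticity, and measurement rounding of real skinfold calipers.
Passing recovery and coverage tests on this generator therefore
demonstrates correctness of the estimation machinery under the stated
model, not robustness to those real-data features.

## Numerical choices

- Quantile rule: type 7 everywhere (knots and quartiles), recorded in
  metadata.
- Conditioning: unit-norm column scaling plus one refinement step; the
  rank check names the collinear columns via pivoted QR on failure.
- Degenerate inputs: constant outcome gives r² = 0; knots outside the
  observed range warn (empty tail interval) but do not error;
  extrapolated grid points in prediction curves are flagged, not
  rejected.
- Printed-value matching in tests uses round-to-printed-decimals
  (4 decimals for slopes and contrasts, 7 for cubic interval
  coefficients), since finer agreement than the printed precision is not
  defined.

## Problem sizes

Test-suite simulations use n = 315 (matching the example) with 500
replicates for the slope-recovery and coverage study, 400 replicates for
the Wald-coverage check, and n = 8000 for the explained-variance
convergence check; the oracle-equivalence suite uses 10 random datasets
(n between 60 and 200) per family. The whole suite runs in well under a
minute on one CPU.
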