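# Methods

## Problem and model

The package estimates the probability that physiological loading drives
the proximal trabecular bone of a PFNA-stabilized intertrochanteric
fracture past its compressive yield strain. Demand is the peak compressive
strain S, approximated by a bivariate quadratic response surface in
apparent bone mineral density (BMD, g/cm³) and hip-contact load (BW,
body-weight multiples):

    S = scale · (a0 + a1·BMD + a2·BW + a3·BMD·BW + a4·BMD² + a5·BW²),

with the published coefficients (4.09, −17.66, 2.80, −2.35, 15.67, −0.05)
at scale 10⁻³. The coefficients are stored exactly as printed plus the
global scale, so the published model is bit-faithful. Capacity is the
compressive yield strain Y ~ N(0.0085, 0.0010) (strain is a dimensionless
fraction everywhere internally; percent appears only in formatting). The
performance function is Z = Y − S; failure is Z < 0, and with normal-Z
assumption PoF = 1 − Φ(μ_Z/σ_Z).

All input variables are treated as mutually independent normals. Age
enters through the BMD mean (50–64: 0.3375, 65–79: 0.2875, ≥80:
0.275 g/cm³), activity through the BW mean (1.56–2.60), and uncertainty
through coefficients of variation σ = μ·COV swept over 0.1–0.9. The 750 N
per BW conversion is metadata only; all computation stays in BW multiples.

## Three strain-moment routes, and why they disagree

`paper_termwise` (reproduction default). Each regressor term — BMD, BW,
BMD·BW, BMD², BW² — is reduced to its own mean and sd using the exact
product/square moment formulas for independent normals:

    μ_p = μ₁μ₂,  σ_p² = (σ₁²+μ₁²)(σ₂²+μ₂²) − μ₁²μ₂²
    μ_q = μ²+σ²,  σ_q² = 4μ²σ² + 4μγσ³ + (κ−1)σ⁴  →  4μ²σ² + 2σ⁴ for normals

and the five terms are then combined *as if independent*:
σ_S² = Σ aᵢ²σᵢ². The derived terms are of course correlated (BMD and BMD²
share one underlying draw), so this systematically overstates σ_S — at the
reference cell (50–64, walking, COV 0.1/0.1) it gives σ_S ≈ 1.00×10⁻³
against the true 6.01×10⁻⁴. It is nevertheless the linearized-combination
recipe that reproduces the published failure probabilities, so it is kept
as a first-class mode and used for reproduction.

`taylor_first_order`. Classic FOSM: μ_S = S at the input means, σ_S² from
the gradient at the means. Exact for linear surrogates, ignores all
second-order (curvature) contributions to both moments.

`exact_moments` (recommended). Substituting BMD = μ_b + σ_b·U,
BW = μ_w + σ_w·V with U, V standard normal rewrites S as a quadratic in
(U, V) whose non-constant terms {U, V, UV, U², V²} are mutually
uncorrelated; the variance is then an exact sum of squares

    σ_S²/scale² = c₁₀² + c₀₁² + c₁₁² + 2c₂₀² + 2c₀₂²

with c₁₀ = σ_b(a1 + a3μ_w + 2a4μ_b) etc. This formulation is exact for
independent normal inputs, accounts for every covariance among the
original terms (Cov(X, X²) = 2μσ²), and is free of the catastrophic
cancellation a raw-moment expansion of E[S²] − E[S]² suffers when the
input sds are small. It agrees with Monte Carlo moment estimates at
n = 10⁶ within sampling error across the COV grid.

All three modes coincide exactly for linear surrogates (a3 = a4 = a5 = 0),
which the suite asserts to 10⁻¹² relative.

The Monte Carlo PoF oracle draws untruncated normals (matching the FOSM
assumptions; truncation at zero BMD is an explicit opt-in for sensitivity
checks). Note that even the exact-moment route feeds a *normal* Z into
1 − Φ(β), while the true Z is yield-minus-quadratic-form; at small tail
probabilities this normality approximation, not the moments, dominates
the residual gap to Monte Carlo (~20% relative at PoF ≈ 0.02%).

## A non-monotonicity the headline ordering hides

Because σ_BMD = μ_BMD·COV ties the spread to the mean, "lower BMD mean ⇒
higher PoF" does **not** hold uniformly over the COV grid. A higher BMD
mean raises σ_S (larger absolute spread) and even raises μ_S through the
a4·(μ²+σ²) mean correction of the BMD² term. In the term-wise mode the
age-group ordering reverses in 236 of 810 adjacent grid comparisons,
starting already at COV_BMD = 0.2 (22 reversals in exact-moment mode; none
in first-order Taylor, which drops the responsible second-order terms).
The monotonicity test over the full grid therefore fails by design and is
left failing as a documented finding; the ordering is asserted only at
COV_BMD = 0.1, plus an explicit reversal check at COV_BMD = 0.9.
Monotonicity in the activity loading mean, by contrast, holds across the
entire grid (a higher BW mean raises μ_S and σ_S together).

## Virtual experiment (synthetic data)

The published surrogate was fit to 100 finite-element simulations with
(BMD, BW) sampled by Latin hypercube from N(0.5, 0.175) g/cm³ and
N(2.0, 0.4) BW. The generator replays that design with the published
surrogate as ground truth plus homoscedastic Gaussian strain noise,
default sd 6.57×10⁻⁴ = √(SSE/n) for the published residual SSE 4.316×10⁻⁵
at n = 100. (The published RMSE figure, 0.0011, is not consistent with
that SSE under any standard definition; the noise default follows the
SSE. Likewise the implementation defines RMSE = √(SSE/(n−p)) and does not
attempt to reproduce the printed 0.0011.) Sampled BMD below 0.01 g/cm³ is
clipped there — a finite-element input must be physical — with a logged
count; clipping applies only to the generator, never to the reliability
oracles.

What the generator does *not* emulate: finite-element discretization
error, heteroscedastic or input-correlated residuals, bone-implant
contact nonlinearity, or inter-specimen geometry variation. Passing
recovery tests therefore show that the fitting and propagation machinery
is correct and unbiased under the stated noise model, not that the
surrogate itself generalizes to real bone.

LHS places one draw per equiprobable stratum, uniformly at random within
the stratum (stratum midpoints available as an option); a single integer
seed drives both the stratum permutations and the within-stratum
positions, so datasets are bit-reproducible.

## Numerical choices

- Degenerate σ_Z = 0: PoF collapses to a step function (1 if μ_S ≥ μ_Y)
  with a warning, not an exception.
- Constant-response fits (SST = 0) define R² = 0 with a warning.
- Rank-deficient surrogate designs raise an error naming the collinear
  regressors (QR-pivot diagnostic).
- The safe/failure boundary in BMD at fixed BW is solved in closed form
  from the quadratic formula; an empty root list means the whole BMD axis
  sits on one side of the criterion (disambiguate by evaluating at
  BMD = 0). Because a4 > 0 the strain parabola opens upward in BMD, so
  large yields always have a crossing at (unphysically) high BMD; roots
  should be interpreted within the trabecular range ≤ 0.9 g/cm³.
- The surrogate dips slightly below zero in the low-load/mid-density
  corner (e.g. S(0.6, 0.5) < 0) — an artifact of the quadratic fit, kept
  as-is for fidelity.
- Under the Pearson constraint κ ≥ 1 + γ², the general square-term
  variance is bounded below by (2μσ + γσ²)² ≥ 0, so it cannot go negative
  for valid inputs; the guard remains for defense in depth.
- Training-envelope warnings for the surrogate use the sampling
  distributions' mean ± 3 sd (BMD ∈ [−0.025, 1.025], BW ∈ [0.8, 3.2]).

## Problem sizes and defaults

Monte Carlo oracles default to n = 10⁶ draws; moment-agreement checks run
on a 3×3 COV grid at that n. Parameter-recovery experiments use 100
replicates of the n = 100 virtual experiment. The full scenario sweep is
3 × 5 × 9 × 9 = 1215 analytic cells. The reported 5% PoF threshold for
flagging clinically concerning cells is configurable
(`DEFAULT_POF_FLAG_THRESHOLD`).

## Known limitations

- The published fit statistics (R² = 0.9334) cannot be re-derived without
  the original finite-element outputs; only the surrogate coefficients
  are carried forward.
- FOSM with normal Z is a tail approximation; for small PoF (< 0.1%) the
  exact-moment route still inherits the normality error (use the Monte
  Carlo oracle there).
- No correlation between BMD and loading is modelled, no fatigue or
  time-variant reliability, and no FORM/SORM design-point search.
- The cortical/trabecular density–modulus laws are provenance only; the
  surrogate already absorbs material behaviour and the PoF pipeline never
  calls them.
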