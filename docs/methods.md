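# Methods

## Design and coding

`build_bbd` generates the three-factor Box–Behnken design only: the 12
edge midpoints {(±1,±1,0), (±1,0,±1), (0,±1,±1)} in a fixed
lexicographic block order plus `n_center` (default 3) centre
replicates. Least-squares fits are invariant to run order, so the
packaged case-study table keeps its original printed order while the
builder uses the canonical one. Factor coding is the affine map
coded = (actual − centre)/half-range; `FactorSpec` rejects a centre
that is not the midpoint of (low, high) because the three-level
design assumes equispaced levels. Centre replicates are what create
pure-error degrees of freedom — `n_center = 1` is allowed but disables
the lack-of-fit test.

## Quadratic fit and ANOVA

The 10-term coded quadratic basis is fit by OLS (statsmodels). All
inference happens in coded units; the coded BBD's main-effect and
interaction columns are mutually orthogonal, which makes the estimates
independent.

Adjusted sums of squares are computed as extra sums of squares: the SSE
increase when the term's column (or, for the grouped Linear / Square /
2-Way rows, the whole group) is dropped and the model refit. On this
orthogonal design the per-term values equal sequential SS. Note that the
grouped Square row is *not* the sum of its members — the squared
columns are not mutually orthogonal — and the implementation follows
the drop-the-group convention that standard DoE software prints; the
Linear and 2-Way groups, being orthogonal, do decompose exactly.

Pure error is the within-group SS over all replicate groups (here the
three centre points, df = 2); lack-of-fit is the remainder of the
residual (df = 3) and is tested against pure error, every other row
against the residual mean square. p-values come from the F
distribution (scipy). Significance is conventionally read at α = 0.05
and α = 0.1; both flags are available. Degenerate inputs: an exactly
interpolated fit (residual SS at round-off level, detected at
1e−14 relative) reports infinite F and t with no significance
threshold; a rank-deficient basis raises an error naming the collinear
columns; negative extra SS beyond round-off is a hard failure.

Standardized effects are t = β̂/se(β̂) with se² = MS_error·(XᵀX)⁻¹ₖₖ,
ranked by |t|; the reference line defaults to the two-sided t critical
value at α with the residual df (2.571 for α = 0.05, df = 5). For any
1-df term t² equals the ANOVA F identically.

On the packaged table the refit reproduces the published coefficients
to within ±0.005. That bound is not slack: the shipped responses are
rounded to two decimals, and each coefficient is a signed average of
4–15 responses whose worst-case rounding perturbation is ±0.005. The
published R² (0.977) is inconsistent with the published ANOVA
(SSR/SST = 1288.6/1307.2 = 0.9857); the package reports the recomputed
value. Likewise the published Pareto reference line (2.09) matches no
t critical value at df = 5, so the threshold is configurable and
defaults to the exact critical value.

## Desirability optimization

Only the maximize goal is implemented (the pipeline optimizes one
maximized response; the composite machinery accepts n responses). The
bounds L and U of d = ((y−L)/(U−L))^w default to L = the minimum
observed response and U = 100, the natural ceiling for a percentage
response, with w = 1; all three are overridable. For the packaged table
this convention gives D = (99.537 − 64.88)/(100 − 64.88) = 0.9868 at
the optimum.

The optimizer scans a dense grid (step 0.01, first-encountered maximum
wins ties in row-major order) and polishes with L-BFGS-B inside the
bounds, evaluating slab-by-slab to keep memory flat. Because d is
monotone in y, maximizing D and maximizing predicted y coincide; the
polish therefore runs on the predicted response and the reported value
is always `predict(model, optimum)` recomputed exactly.

On the case-study surface the maximizer is (0.1739, −0.2281, 1.0) with
predicted removal 99.5365 %. The study's profile optimizer printed
(0.1717, −0.2323, 1.0) — the surface is a ridge so flat that the two
points differ by ~1e−4 percentage points, and the study's own
crow-search run reports the former coordinates. The package returns
the true maximizer and does not reproduce the profile-printed
coordinates beyond ~0.004 in the temperature coordinate.

## Crow search

Flock defaults N = 50, fl = 2, AP = 0.1 (the algorithm's canonical
settings — the case study does not state its values) with 150
iterations; all overridable. Per iteration and crow the draws are made
in a fixed order (followed crow j, awareness uniform, step uniform,
restart block) so runs are bit-reproducible from the seed regardless of
which branch each crow takes. Positions leaving the box are clamped
component-wise (keeps the evaluation count deterministic; resampling
until feasible is the common alternative). "Better" in the memory
update means strictly greater, so ties keep the older memory.
Multi-run statistics use per-run seeds master + run index and report
best/worst/mean/sample-std of the per-run bests. On the case-study
surface 50 runs of 150 iterations agree to ~1e−11 — consistent with
the tiny spread the study reports (1.4e−5), whose exact value depends
on its unstated hyperparameters. The study's "stable after 56
iterations" observation is seed-dependent and is not asserted anywhere.

## Kinetics

Uptake and removal bookkeeping are exact identities
(q_t = V(C₀−C_t)/m; R = 100·m·q_t/(V·C₀) at any time). Both rate laws
are fit in their linearized forms by least squares (scipy linregress):

* pseudo-first order on (t, log₁₀(q_e,exp − q_t)): k₁ = −slope·ln 10,
  q_e,calc = 10^intercept. The conventional 2.303 divisor is ln 10
  rounded; the exact constant keeps noiseless round trips exact. The
  caller supplies q_e,exp (the observed plateau); the pipeline defaults
  to the final q_t with a logged note. Points at or above q_e,exp are
  excluded (log domain) and counted.
* pseudo-second order on (t, t/q_t): q_e,calc = 1/slope,
  k₂ = slope²/intercept; non-positive slope or intercept means the
  model is inapplicable and raises.

The published kinetic parameters are shipped as fixture constants for
synthetic generation and recovery tests, not as refit targets — the raw
trace behind them was never printed. Those published conditions are
internally inconsistent (q_e = 3.727 mg/g at 1.5 g/L dose and C₀ = 10
mg/L implies ≈56 % removal, not the ≈97 % reported); the package
computes both quantities and leaves the discrepancy visible (the
kinetics example prints it) rather than resolving it.

The first-order linearization is noise-fragile near the plateau, where
log(q_e − q_t) amplifies measurement error without bound; recovery
tests therefore sample it before ~3 time constants. This is a property
of the linearization itself, not of the implementation.

## Synthetic data

`generate_bbd_responses` evaluates a known coefficient vector at the
design points and adds i.i.d. Gaussian noise; centre replicates get
independent draws, which is exactly the data-generating process the
pure-error estimator assumes. Defaults emulate the case study: truth =
the published coefficients, σ = √3.725 (the published error mean
square). `generate_kinetic_trace` inverts the closed forms
q_t = q_e(1 − e^(−k₁t)) and q_t = q_e²k₂t/(1 + q_e k₂ t) through the
mass balance C_t = C₀ − m·q_t/V, validates feasibility
(q_e·m/V ≤ C₀), adds Gaussian noise on C_t and grants the trace a 5σ
validation allowance above C₀.

What the generators do not emulate: real response surfaces are only
locally quadratic, real noise can be heteroscedastic and correlated
in time, and multi-metal competition is not simulated (the
electronegativity ranking is a stable descending sort, predicting the
observed order only up to the near-tie between Cu and Co). Passing
recovery tests therefore demonstrate correctness of the estimators
under the model's own assumptions, not validity of those assumptions
for any particular dataset.

## Problem sizes and determinism

The packaged experiment is 15 runs; Monte-Carlo checks use 100–200
replicates, crow-search verification 50 runs × 150 iterations × 50
crows, and grid oracles 201³ points evaluated in vectorized slabs —
all chosen so the full suite completes in well under a minute on one
core. Every stochastic path takes an explicit seed or generator;
pipeline outputs embed the seed in a header comment and runs with the
same seed are byte-identical.
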