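# Methods

## Model

`nasalpk` implements a mammillary two-compartment open model with two
parallel first-order absorption routes, intended for intranasal ("nose to
brain") delivery studies with an IV bolus reference arm.  States are
amounts (ng): a depot at the absorption site, a central compartment (plasma
plus well-perfused organs), and the brain.  Assumptions, all of which the
closed forms rely on:

* all processes are first-order (linear kinetics, appropriate at low dose —
  the canonical study uses ~0.36–0.39 mg/kg);
* drug release/dissolution at the absorption site is immediate, so the
  depot empties with the single overall rate `Ka = Ka1 + Ka2`;
* elimination occurs only from the central compartment (`K10`); the brain
  returns drug exclusively via `K21`;
* no lag time, single dose, no recirculation pathways beyond `K12`/`K21`.

The plasma solution is the triexponential
`C(t) = C1·e^(−Ka t) + C2·e^(−λ1 t) + C3·e^(−λ2 t)` with `Ka > λ1 > λ2 > 0`
and hybrid rates defined by `λ1+λ2 = K12+K21+K10`, `λ1λ2 = K21·K10`.  The
brain amount is the four-pole partial-fraction inversion of
`X̄2 = K12·X̄1/(s+K21) + Ka2·F·D/[(s+K21)(s+Ka)]`; when the hybrids derive
from the same micro-constants the residue at `−K21` vanishes identically,
leaving three effective terms.  Coefficients are stored **signed** (the
absorption coefficient is negative; for an exactly model-generated curve the
three plasma coefficients sum to zero).  Reports print magnitudes with a
sign flag, matching how PK tables are conventionally typeset.  Fitted
coefficients are *not* forced to sum to zero by default (`constrain_c0`
turns that on): mean profiles assembled from destructively sampled animals
routinely violate `C(0)=0`, and the default mirrors common compartmental
packages.

The rate ordering `Ka > λ1 > λ2` is asserted, never assumed: parameter sets
implying flip-flop absorption raise immediately.  Coincident rates
(relative separation below 1e−9) raise a degenerate-pole error; confluent
`t·e^(−kt)` solutions are deliberately not provided, since no admissible
fit should land exactly on a pole collision and silent switching would mask
inconsistent inputs.

`V2`, a brain volume of distribution, is carried on the parameter container
for completeness but enters no equation.  Brain observations are treated as
amounts (ng); a concentration reading would only rescale the brain profile
by a constant and changes no rate constant.

## Estimation

**Fitting.**  Weighted nonlinear least squares on the polyexponential, with
a separable (variable-projection) parameterisation: the nonlinear search
runs over log rates only, and at every iterate the coefficients are the
exact solution of the weighted linear least-squares subproblem.  This
matters because in the canonical parameter set `Ka = 0.1112` sits within 6%
of `λ1 = 0.1051`: a fully joint 6-parameter search stalls in the
near-degenerate valley, whereas the profiled objective in 3 rate parameters
is well behaved.  A small multistart (absorption-rate seed scaled by 0.5,
2 and 5) guards against the remaining local minima.  Rates are clipped to
`e^(±30)`…`e^10` min⁻¹ inside the search purely to avoid overflow.
Non-convergence is reported on the result object, never raised.

**Weighting.**  Default `1/y` (a compromise between absolute and log-scale
error, and a common default in compartmental tools); `uniform` and `1/y²`
are selectable.  `1/y²` reproduces log-space least squares to first order
in the residuals.  Observed values are floored at `1e−8·max(y)` inside the
weights so zeros cannot produce infinite weights.

**Starting values.**  Classical curve stripping (method of residuals):
log-linear terminal fit for `(C3, λ2)`, peeling for the faster phases, with
the absorption phase peeled from the *negated* second residual.  Peels are
accepted only when residuals exceed `1e−9·max(y)` (guarding against peeling
float noise) and preserve the rate ordering; otherwise a heuristic start is
substituted (rates spaced geometrically above the terminal slope,
coefficients by linear least squares) and flagged.  Peeled coefficients are
kept when every peel succeeds; stripping accuracy of ~5% holds for
well-separated phases, which is all an initializer needs.

**NCA.**  Linear trapezoid to the last observation plus `C_last/λz`
extrapolation; `λz` from a log-linear regression on the last 4 points by
default (user-overridable — the choice is conventional).  Profiles that do
not start at t = 0 are anchored at (0, 0) for extravascular and brain data
and log-linearly back-extrapolated to `C(0)` for IV plasma, following
standard NCA practice.  A non-positive terminal window yields `λz = NaN`
with AUC(0–last) still returned.

**Pooling.**  The destructive-sampling design gives each animal one
timepoint, so estimation operates on the group mean profile per (route,
matrix) — the naive pooled approach.  Per-animal or mixed-effects fitting
is out of scope and unidentifiable under this design anyway.  Plasma values
below the 1 ng/mL LOQ of the reference bioanalytical assay are excluded
(not imputed) before averaging, with the exclusion count carried on the
profile.

## Derivation chain

The chain from fitted macro-constants to reported quantities is:
IV biexponential → `K21 = (C2λ2+C3λ1)/(C2+C3)`, `K10 = λ1λ2/K21`,
`K12 = λ1+λ2−K21−K10`; intranasal hybrids + IV `K10` →
`K21(IN) = λ1λ2/K10`, `K12(IN) = λ1+λ2−K21−K10`; then the absorption split
via `N = (Ka−λ2)/(λ1−Ka)`, `r = C2/(N·C3)`,
`Ka2 = [r·Ka(K21−λ2) − Ka(K21−λ1)]/(λ1 − r·λ2)`, `Ka1 = Ka − Ka2`.  The
split algebra was re-derived from the closed-form coefficient ratio and is
validated by a forward-model oracle: coefficients generated from 200 random
admissible parameter sets invert back to every micro rate within 1e−8
relative.  A `Ka2` outside `[0, Ka]` raises with the raw value attached —
it diagnoses mutually inconsistent fits and is never clipped.

Bioavailability is dose-corrected by default
(`100·AUC_t·D_r/(AUC_r·D_t)`); a flag exposes the plain AUC ratio.
`K_in`, the aggregate brain input rate constant (`K12_brain` for IV,
`Ka2 + K12_brain` for IN), requires a brain-side `K12` that a plasma-driven
analysis cannot identify; the pipeline reports it only when that value is
supplied in the run configuration, and `brain_kin` computes it from
explicit inputs.

## Synthetic studies

`simulate.generate_study` emulates the destructive-sampling rat experiment:
default grid {5, 10, 15, 20, 30, 45, 60, 90, 120, 180, 240, 360} min
(early-dense to resolve a ~10–15 min plasma peak, extending to 6 h to pin
the terminal phase), 6 animals per timepoint per route, 100 µg (1e5 ng)
doses, body mass 0.275 ± 0.015 kg.  Each virtual animal contributes one
paired plasma concentration and brain amount: the closed-form model mean
times an independent multiplicative lognormal deviate with mean exactly 1
and CV 0.15 — a standard residual model for LC-MS/MS bioanalysis.  The
canonical truth is the fitted rat parameter set (`K10 = 0.0275`,
IV `K12/K21 = 0.0897/0.0146`, IN `K12/K21 = 0.0697/0.0107`,
`Ka1/Ka2 = 0.0489/0.0623` min⁻¹, `V1 = 276` mL, `F = 0.479`).

What the generator does *not* emulate: between-animal variability in the
rate constants (unidentifiable under pooled-mean analysis), assay bias,
nanoparticle release kinetics, and any brain elimination.  Passing recovery
tests therefore demonstrate correctness of the estimation chain under the
model's own assumptions — not robustness to model misspecification in real
data.  Two concrete consequences: the model's brain peak under the
canonical truth falls near 40 min (the real study observed ~10 min), and
the model's brain/plasma ratio rises monotonically to a plateau, whereas
measured ratios peak and decline — both reflect processes (fast early BBB
flux, brain loss) outside the model, and the shape tests assert the
model-true behaviour.

Calibration runs frozen as regression bounds use 200 replicate studies at
CV 15%, n = 6/timepoint: the mean recovered bioavailability stays within
10% of truth, and the fitted intranasal terminal rate λ2 falls within 25%
of truth in at least 90% of replicates.  Individual-replicate estimates of
`Ka1/Ka2` are far noisier (the `Ka ≈ λ1` geometry makes the absorption
phase weakly identified at this noise level) and are deliberately not
bounded per replicate.

## Numerical choices

* ODE oracle: LSODA (stiff-capable), rtol 1e−10 / atol 1e−12; closed forms
  agree with it to better than 1e−6 sup-norm, mass balance to 1e−8.
* Hybrid roots: stable quadratic form (`λ1` from the positive branch,
  `λ2 = K21·K10/λ1`) so the small root never suffers cancellation.
* Pole-coincidence tolerance 1e−9 relative throughout.
* Tiny negative `K12` from cancellation (below 1e−12 of the rate scale) is
  clamped to zero; genuinely negative values raise a diagnostic error.
* All units fixed: minutes, ng, mL, ng/mL, min⁻¹.

## Known limitations

* Single-dose, linear kinetics only; no infusion, lag time or multiple
  dosing.
* The absorption split is exquisitely sensitive to the fitted `C2/C3` ratio
  when `Ka ≈ λ1`; on noisy data the triexponential fit can return a
  near-degenerate `Ka ≈ λ1` pair with large cancelling coefficients.  The
  fit is flagged converged only when the rates remain separated, and the
  derivation chain raises rather than propagating an inadmissible split.
* Brain-side rate constants beyond `K21` (a brain `K12`, hence `K_in`) are
  not identifiable from this design and must be supplied externally.
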