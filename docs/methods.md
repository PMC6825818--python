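# Methods

## The model

`vitakin` implements the standard seven-component linear compartmental
description of whole-body vitamin A (retinol) kinetics in humans.  An oral
tracer dose and dietary vitamin A `U(1)` enter gastrointestinal
compartment 1; a fraction `a` (absorption efficiency, default 0.75) moves
through absorptive compartment 2 and delay component 3 (`DT(3)` days,
chylomicron processing) into hepatocyte compartment 4, from which retinol
bound to retinol-binding protein is secreted into plasma compartment 5.
Plasma retinol exchanges with two extravascular pools: a large slow store
(compartment 6) and a small fast pool (compartment 7).  Total body stores
are `TBS = M(6) + M(7)`.  Irreversible loss leaves from compartment 6 by
default (`L(10,6)`), or from both stores in the dual-loss variant.  All
transfers are first-order with fractional transfer coefficients `L(I,J)`
(fraction of compartment J moved to compartment I per day); units are
days, micromoles, micromoles per day.

Unabsorbed dose is modeled as a gut loss `L(0,1) = L(2,1)(1-a)/a`, which
makes the absorbed fraction exactly `a` without fitting it.

### Tracer solution

The tracer system is solved in closed form.  The delay is exact, not
discretized: because the absorptive chain feeds the post-absorptive block
one-way and that block is linear, time-invariant and initially empty, the
response of compartments 4-7 to the delayed input equals their response to
the undelayed input shifted by `DT(3)`.  We therefore eigendecompose the
6x6 no-delay rate matrix once, evaluate states (and their running
integrals, for mass-balance accounting) at `t` for the upstream
compartments and at `t - DT(3)` for the downstream ones, and reconstruct
the delay content from the difference of cumulative pool-2 outflows.  A
dense matrix-exponential backend (augmented with integral states) is the
fallback whenever the eigenbasis is ill-conditioned, and an Erlang-chain
approximation of the delay (default 20 stages) is available for
comparison.  Tracer mass is conserved to ~1e-15 on a unit dose.

### Steady state

With the plasma pool `M(5)` fixed (measured, never fitted), flux balance
gives closed forms: `M(6) = M(5) L(6,5) / (L(5,6) + L(10,6))`, `M(7) =
M(5) L(7,5) / (L(5,7) + L(10,7))`, disposal rate `DR = M(6) L(10,6) +
M(7) L(10,7)`, predicted intake `DR / a`, and days of stores `TBS / DR`.

### Derived kinetics

Transit time `1/(L(6,5)+L(7,5))`, plasma residence time `[-A^{-1}]_{55}`
of the post-absorptive 5/6/7 subsystem, recycling number `RT/TT - 1`, and
recycling time (mean extravascular sojourn per plasma return) come from
the negative inverse of the subsystem matrix — the mean-occupancy
formulation standard in tracer kinetics; a Monte-Carlo jump-chain oracle
checks them in the tests.  The absorptive chain is excluded from these
statistics (it is a one-way feed).  Crossover time — the first day store
specific activity `(q6+q7)/TBS` exceeds plasma specific activity
`q5/M(5)` — is found on a daily grid refined by bisection to 0.01 d, on
the full oral-dose simulation.

## Synthetic cohort

Twelve fixture subjects (4 children, 4 younger adults, 4 older adults)
are *designed*: state-variable targets are inverted exactly through the
steady-state relations (`L(10,6) = DR/M6`, `L(5,6) = M5 L(6,5)/M6 -
L(10,6)`, `L(5,7) = M5 L(7,5)/M7`), so every subject's reference solution
is consistent by construction.  Targets span the ranges reported for
these groups: TBS 31-3000 umol (children 31-1100, younger adults
210-1030, older adults 460-3000), intakes 0.53-4.3 umol/d, days of stores
78-1250.

Exchange kinetics follow the human retinol literature: plasma transit
times of a few hours and extensive recycling (recycling numbers ~10-40).
The large store's return time `1/(L(5,6)+L(10,6))` grows with vitamin A
status, from ~8 d in the smallest child to ~45 d in the highest-TBS older
adult, so crossover time increases with TBS across the cohort (~6-20 d).
The fast pool's return rate and exchange share were fixed by an
information criterion evaluated at the true parameters (design FSDs from
the weighted Jacobian): every adjustable coefficient identifiable from a
full-length 5%-noise study, and TBS well-determined from 114 d of data.
The absorptive phase uses `L(2,1) = 3 /d`, pool-2 turnover `L(4,3) = 6
/d`, `DT(3) = 0.1 d` and hepatic secretion `L(5,4) = 3 /d`.

Noisy studies sample the 24-point schedule (3, 5, 8, 12 h; 1, 2, 4, 7,
10, 14, 21, 28, 35, 42, 49, 56, 70, 84, 114, 144, 200, 260, 310, 365 d)
with multiplicative normal error of fractional standard deviation (FSD)
0.05, clamped at a tiny positive floor so relative weighting never
divides by zero.  `make_cohort(seed)` samples fresh range-matched
cohorts; the fixture is the deterministic default.

What the generator does **not** emulate: real plasma data have
non-stationary, possibly correlated assay error; real subjects violate
the steady-state assumption (growth, infection, varying intake); real
absorption varies between meals.  Passing tests therefore demonstrate the
*method's* behavior under its own assumptions, not field performance.

## Fitting

Weighted nonlinear least squares over (by default) `L(6,5), L(7,5),
L(5,6), L(5,7), L(10,6), L(5,4)` with `L(2,1)`, `L(4,3)`, `DT(3)` and
`M(5)` fixed at assigned values.  Residuals are `(obs - pred)/(fsd *
obs)` with fsd = 0.05 — the observed-value FSD-weighting convention of
SAAM-style software — plus, when the dietary-intake datum is included,
one more residual `(U - DR/a)/(fsd * U)` from the steady state.  The
optimizer is scipy's bounded trust-region-reflective least squares
(bounds `L >= 0`, so a terminal slope can legitimately converge to zero;
`ftol = xtol = 1e-10`), with up to 5 restarts from log-normally perturbed
starts if a solve fails.  Parameter FSDs (CVs) come from the Gauss-Newton
covariance `(J^T J)^{-1}`, both scaled by the reduced chi-square and
unscaled (the scaling convention of the original software is not
documented, so both are reported; the scaled one is used for the
identifiability criterion).

The fitting surface is a scikit-learn estimator
(`RetinolKineticsModel.fit(times, fd) / predict / get_params`), with
`fit_model`, `wnls_objective` and `parameter_fsd` as functional wrappers.

## Reference values and accuracy criteria

Reference values for each subject are obtained by the same workflow
applied to the data: fit the full-length (365-d) noisy study without the
intake datum, then solve the steady state with the assigned `M(5)`.
Accuracy criteria therefore measure what is lost by *shortening* the
study, not the fit's irreducible error against the generating truth (the
full-length anchor of every scan passes its own criteria by
construction).  The intake datum used in with-intake fits is the
reference intake.  Two modes:

* **TBS-only**: TBS within 15% of reference.
* **Full system**: additionally intake, M(6), M(7), DR and all adjustable
  coefficients within 25%; all adjustable-coefficient FSDs < 0.5
  (identifiability cutoff); and `L(10,6) > 1e-6 /d` — subjects consume
  vitamin A, so true isotopic equilibrium is never reached and a zero
  terminal slope marks an under-determined fit.

## Truncation scans

The scan runs from the full study length *downward* on the sampling grid,
each refit warm-started from the previous (longer) fit, stopping at the
first failure; the shortest accurate duration is the last passing grid
time.  The first (365-d) fit starts from the reference coefficients
perturbed x1.3 for return/loss coefficients and /1.3 for plasma-exchange
coefficients.  The perturbation cannot be uniform — steady-state masses
are homogeneous of degree zero in the coefficients, so a uniformly scaled
start would already reproduce the reference TBS — and this orientation
starts the fit with a steeper-than-true terminal slope, the canonical
truncation failure mode (disposal overestimated, stores underestimated).
The with-intake scan starts at the duration identified without intake.
The noise realization is fixed per subject across a scan.  Scan-level
conclusions near criterion boundaries are asserted as medians over >= 5
noise seeds.

Degenerate behaviors worth knowing about: on short noisy datasets the
weighted objective has a nearly flat ridge along which `L(10,6)` and
`L(5,6)` fall together while implied stores grow; fits on that ridge can
*over*estimate TBS (the "slope converged to zero" failure), and whether a
failing short fit lands above or below the reference is decided by the
noise realization, not by the starting point — both outcomes are global
optima on different noise draws.  The full-system criteria (positive
terminal slope, FSD cutoff) are what detect this ridge.

## Intake sensitivity and RID

Sensitivity refits each subject at its shortest accurate with-intake
duration with the intake datum at 50% and 150% of the reference value,
warm-started from the reference-intake fit, and reports TBS ratios.

The super-person analysis forms pointwise geometric-mean curves per group
(the log of the geometric mean is the mean of logs, so the group curve's
terminal log-slope is the mean of the members'), a group model whose
fixed quantities are geometric means of the members', and computes the
composite RID coefficient as `FaS(t) = TBS * FD_p(t) / M(5)` — the unique
dimensionless coefficient that makes the RID identity `TBS = FaS *
M(5)/FD_p(t)` exact under the fitted model.  The published RID
coefficient definition is not printed in the primary sources, so this
operational definition is used consistently for reference (365-d
geometric-mean fit without intake) and truncated fits; ratios between
them are then formula-independent.  The truncated with-intake fit uses
the arithmetic group mean of the members' reference intakes as its datum
(dietary intakes are conventionally averaged arithmetically).

## Dual-loss variant

`dual_loss_variant` re-parameterizes a subject with irreversible loss
from both stores at the same fractional catabolic rate `DR/TBS`
(mass-proportional split; a `share_6` parameter overrides it), leaving
every state variable unchanged.  Fitting such data with both the
dual-loss model (7 adjustable coefficients) and the lumped
single-loss-from-6 model measures the cost of lumping the loss site.

Known limitation: the dual model's extra coefficient `L(10,7)` is a
nearly flat likelihood direction under plasma-only sampling; a global
optimizer settles wherever the noise realization puts it along that
ridge, so the two fits' TBS predictions can differ by up to ~10% on 5%
noise even though the noiseless (pure misspecification) gap is under 1%.
A damped local optimizer that barely moves `L(10,7)` from its start
would make the two fits nearly coincide.

## Problem sizes and numerical choices

Default experiment sizes: 12 subjects, 24-point schedule, 5 noise seeds
for scan-level medians; a full pipeline run is ~200-400 weighted fits.
Tie-breaks and edge cases: `L(10,6) = 0` during optimization is allowed
(bounds, not log-transforms) and the steady state is then reported as
undefined rather than infinite; eigen-solves fall back to dense matrix
exponentials past condition 1e10; crossover search starts after
`DT(3) + 1` d and reports not-reached past 365 d; fits with fewer
observations (plus datum) than parameters are refused.
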