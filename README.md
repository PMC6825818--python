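# vitakin

Model-based compartmental analysis of whole-body vitamin A kinetics, for
nutrition scientists who estimate vitamin A total body stores (TBS) from
plasma retinol tracer studies and need to know **how long such a study
must run** — and how much shorter it can be when an estimate of dietary
vitamin A intake is added to the modeling data stream.

## The model and the question

Whole-body retinol kinetics are described by a seven-component linear
compartmental model: oral tracer and dietary vitamin A `U(1)` enter the
gut (compartment 1), pass an absorptive chain (2, delay 3, liver 4) into
plasma (5, the sampled pool, size `M(5)` fixed), which exchanges with a
large slow store (6) and a small fast pool (7); irreversible loss leaves
from compartment 6.  Transfers are fractional transfer coefficients
`L(I,J)` (/d).  At steady state, with absorption efficiency `a = 0.75`,

    M(6) = M(5) L(6,5) / (L(5,6) + L(10,6)),   TBS = M(6) + M(7),
    DR   = M(6) L(10,6),                       intake = DR / a.

Tracer curves `FD_p(t)` (fraction of oral dose in plasma) are fit by
FSD-weighted nonlinear least squares; an intake estimate enters as one
extra weighted steady-state datum.  Because `L(10,6)` is defined by the
terminal slope of the tracer curve, short studies leave it — and hence
TBS — poorly determined; the intake datum anchors it.

The package provides the forward solver (exact transport delay, closed
form), a designed 12-subject synthetic cohort spanning TBS 31-3000 umol,
the weighted fitter (a scikit-learn style estimator), derived kinetic
parameters (transit/residence/recycling/crossover times), truncation
scans for the shortest accurate study duration, intake-misspecification
sensitivity, and group ("super-person") retinol isotope dilution (RID)
coefficients `FaS`.

## Worked example

How long must a tracer study run for a younger adult with ~430 umol of
stores, without and with the intake datum?

```python
from vitakin import (make_cohort, generate_dataset, reference_fit,
                     duration_scan, AccuracyCriteria)

cohort = make_cohort()                      # the 12 fixture subjects
y6 = next(s for s in cohort if s.id == "Y6")
study = generate_dataset(y6, fsd=0.05, seed=5005)   # noisy 24-point study
ref = reference_fit(study, y6)              # 365-d reference workflow
print(f"reference TBS = {ref.steady_state.TBS:.0f} umol "
      f"(design {y6.reference.TBS:.0f}), intake = {ref.intake:.2f} umol/d")

full = AccuracyCriteria(mode="full")
tbs = AccuracyCriteria(mode="tbs")
without = duration_scan(study, y6, with_intake=False, criteria=full,
                        stop_criteria=tbs, reference=ref)
d_wo, n_wo = without.shortest_passing()
with_dat = duration_scan(study, y6, with_intake=True, criteria=full,
                         stop_criteria=tbs, reference=ref, start_duration=d_wo)
d_wi, n_wi = with_dat.shortest_passing()
print(f"shortest accurate duration: {d_wo:.0f} d ({n_wo} samples) without intake")
print(f"                            {d_wi:.0f} d ({n_wi} samples) with intake "
      f"(-{100*(d_wo-d_wi)/d_wo:.0f}%)")
```

prints

```
reference TBS = 423 umol (design 430), intake = 2.20 umol/d
shortest accurate duration: 114 d (19 samples) without intake
                            10 d (9 samples) with intake (-91%)
```

The 365-d fit recovers this subject's stores within 2% and its intake
exactly enough to serve as the reference.  Without the intake datum the
truncation scan needs 114 d of data (19 blood samples) before TBS, the
other state variables and all rate coefficients stay within the accuracy
criteria; adding the single intake datum shortens that to 10 d and 9
samples — a 91% reduction.  `AccuracyCriteria(mode="tbs")` gives the
looser stores-only analysis, and `fixed_duration_evaluation`,
`intake_sensitivity` and `group_fas_table` cover the companion analyses
(28 d / 56 d protocols, 50-150% intake misspecification, RID
coefficients).  The same functionality is scriptable via the `vita` CLI
(`vita simulate`, `vita fit`, `vita scan-duration`, `vita reproduce`,
...).

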