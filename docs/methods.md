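# Methods

## Model structure and assumptions

The model couples a 30-day decision tree to a monthly-cycle Markov cohort
model over seven health states: modified Rankin scale (mRS) 0–5 and death.
The cohort enters at age 65 after an acute mild-to-moderate ischemic
stroke (IS) or TIA and is followed for 30 years (360 cycles). Two
strategies differ only in the first 30 days: aspirin alone, or ticagrelor
added to aspirin (the ¥394 course cost and the trial-observed shifts in
30-day outcomes).

**Acute phase (cycle 1).** The 30-day probability of the primary outcome
(composite of stroke or death) is 0.066 under aspirin; the intervention
arm's probability is obtained on the hazard scale, 1 − (1 − p)^HR with
HR = 0.83. The printed proportions of death/IS/ICH among primary outcomes
overlap slightly (they sum to 1.045 and 1.096), because fatal strokes
appear in two categories; they are renormalized to a partition before
multiplying by the primary-outcome probability. These decomposed event
probabilities drive acute costing and disutility only. The Markov entry
state vector is taken directly from each arm's printed 30-day mRS 0–5
distribution, with death as the residual (0.006 aspirin, 0.007
ticagrelor): the disability distribution is the direct outcome
measurement, whereas the decomposition is a derived quantity.
Hospitalization tariffs are given by dependency only, so the IS and ICH
tariffs are mixed using the arm's own split of surviving mRS mass into
independent (mRS 0–2) and dependent (mRS 3–5).

**Markov phase (cycles 2–360).** At each cycle boundary the transition
applies, per alive state: background non-stroke death; then, among
survivors, recurrent stroke; fatal recurrences (probability 0.193) go to
death, non-fatal ones are reallocated uniformly over the states of equal
or greater disability (mRS 2 → ¼ each to 2,3,4,5); everyone else stays.
Recurrence risk is state-independent, and the monthly probability
converts the annual rate (0.122) on the hazard scale with a stepwise
escalation factor 1.03^⌊years since entry⌋. A recurrence is an ICH with
probability 0.075, otherwise an IS; event tariffs follow the type, the
fatality (fatal IS takes the IS-death tariff, fatal ICH the
dependent-or-death tariff), and, for survivors, the post-reallocation
dependency mix.

**Reward timing.** Cycle *t*'s occupancy is the post-transition state,
and rewards accrue on it (the transition-reward convention of
decision-analysis software): state utility u(s)/12 and, from cycle 2
onward, monthly maintenance cost (annual cost / 12, by dependency) per
occupied state, plus event tariffs and disutilities on the transitions
into the cycle. Both streams are discounted by (1.03)^(−(t−1)/12); cycle
1 carries the acute-phase cost and QALY at factor 1. No half-cycle
correction is applied. This convention makes the engine exactly match
the closed-form geometric-series oracle Σₜ ((1−d)·δ^(1/12))^(t−1)·u/12
for a constant-hazard cohort, which the tests require to 10⁻⁹.

**Event disutilities are one-time decrements.** The 0.66 (recurrent
stroke) and 0.2 (major ECH) disutilities are subtracted once per event in
QALY units, not prorated to the one-month cycle. The alternative reading
(a one-cycle decrement of 0.66/12) was implemented and rejected: it caps
the contribution of the between-arm difference in event rates to the
incremental QALY at ~0.0006 — treating a prevented stroke as worth about
two days of quality-adjusted life, far below the measured disability
burden of a stroke event — and it makes the cost-effectiveness
conclusion fragile under PSA (≈97 % instead of ≈99.9 %). The one-time
decrement is also the native behavior of transition rewards in the
decision-tree software this class of models is typically built in. The
disutility is attributed to the state of origin and each state's QALY
increment is floored at zero.

## Background mortality

Annual all-cause death probabilities qx come from an age-indexed life
table; the stroke-attributable share of deaths is removed (stroke deaths
are modeled explicitly through recurrence) and the monthly probability
for state s is 1 − exp(−(−ln(1−qx)·(1−f)/12)·HR(s)), with mRS-specific
hazard ratios 1.00, 1.00, 1.11, 1.27, 1.71, 2.37. Twelve monthly
survival factors compound exactly to the annual non-stroke survival.

Two calibration inputs deserve emphasis because no official table ships
with the package:

* **The life table** defaults to a Gompertz fixture, qx(a) =
  1 − exp(−h₀·e^(0.09(a−65))) over ages 65–110, with h₀ solved by
  bisection so that remaining life expectancy at 65 is 19 years (of the
  order of recent Chinese period life tables). Any table can be loaded
  from CSV (`age,qx`).
* **f_stroke = 0.22**, the share of all-cause deaths removed as
  stroke-attributable, of the order of the cerebrovascular share among
  Chinese causes of death. It is a plain argument to every life-table
  constructor.

Absolute lifetime costs and QALYs are strongly sensitive to this
calibration (the cohort's discounted life expectancy scales both nearly
proportionally), while the ICER is much less so: the acceptance suite
sweeps e₆₅ over 18–20 years and verifies the cost-effectiveness
conclusion is unchanged. Comparisons of absolute levels against any other
implementation are only meaningful with that implementation's life table.

## Parameters and distributions

All inputs live in a single registry with base value, plausible range,
and sampling distribution (beta for probabilities and utilities, gamma
for costs, lognormal for relative risks), parameterized from their
natural-scale mean and SD by the method of moments. SD = 0 degenerates
to a point mass. Key defaults: discount rate 3 %/year; WTP ¥72,447/QALY;
horizon 30 years; cycle 1 month; entry age 65. Configs are flat YAML/JSON
key–value files; unknown keys are rejected and every value is validated
(bounds, mRS-proportion sums, monotone mortality HRs and utilities) with
the offending parameter named.

## Sensitivity analyses

* **One-way:** each input with a printed range is set to its endpoints,
  all else fixed; mortality HRs, which have distributions but no printed
  range, use mean ± 1.96 SD; the 30-day mRS proportions and the analysis
  settings, which have neither, are excluded. Probability endpoints are
  truncated to [0, 1]. Entries are sorted by ICER span.
* **PSA:** every distributed input is drawn once per iteration from a
  single seeded generator in fixed registry order — shared inputs (costs,
  utilities, recurrence parameters, mortality HRs) apply to both arms,
  arm-specific 30-day inputs only to theirs; parameters are sampled
  independently, and distributions are recentered at the current
  (possibly overridden) value with the registry SD. Outputs: per-iteration
  draws and (ΔC, ΔE), the fraction cost-effective at the WTP, and the
  acceptability curve over a ¥0–150,000 grid. Identical seeds reproduce
  byte-identical sample files.
* **Subgroups:** the primary-outcome HR is replaced by a subgroup's
  mean/low/high estimate with all else at base case. Subgroup HR tables
  are user-supplied CSVs; the bundled template carries only the overall
  trial row (0.83, 0.71–0.96).

## Synthetic scenarios: what they do and do not show

The generators in `stroke_cea.synthetic` exercise the machinery, not the
epidemiology. The null scenario (arms forced identical, arm-specific
distributions degenerated to points) checks exact symmetry through the
whole pipeline including PSA. The constant-hazard scenario checks the
engine against a closed-form geometric series to 10⁻⁹. Perturbed
scenarios draw inputs uniformly within the printed ranges (with a
running-minimum fix-up to keep utilities monotone) to sweep invariants
such as occupancy conservation at range extremes. Passing these says the
cohort arithmetic is right; it says nothing about whether the trial-based
inputs, the uniform reallocation rule, or the state-independent
recurrence assumption describe real post-stroke populations — the last
two are known simplifications inherited from this model family.

## Numerical choices and limitations

* Occupancy is conserved to <10⁻¹² per cycle by construction; death
  occupancy is non-decreasing.
* Escalation uses integer elapsed years; age enters qx lookup at its
  integer floor; both are standard cohort-model conventions.
* ICERs are undefined (reported as missing) when ΔE = 0; dominance is
  reported via a status field rather than a negative ratio.
* The between-arm difference in 30-day death (0.007 vs 0.006) is the
  residual of distributions printed to three decimals, so the downstream
  component of the incremental cost carries rounding-level uncertainty of
  the same order as the quantity itself; incremental costs below ~¥100
  should not be over-interpreted.
* Deterministic pipeline evaluations take ~25 ms, a 10,000-iteration PSA
  ~3 s (the engine is vectorized across iterations); these sizes are the
  package defaults throughout.
* No tunnel states, no memory of prior recurrences, no treatment
  switching after day 30, no currency conversion, and no EVPI.
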