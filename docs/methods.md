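# Methods

## Model structure

Five health states: *no pain* (NRS 0), *mild* (NRS 1–3), *moderate*
(NRS 4–6), *severe* (NRS 7–10) and absorbing *dead*. Cycles are one month;
the cohort enters at age 32 and runs to age 50 (216 cycles). Transitions
between pain states are restricted to adjacent severity levels within one
cycle. All-cause mortality applies identically from every alive state —
endometriosis itself carries no excess mortality — by converting the life
table's annual probability to a monthly one, `q_m = 1 − (1 − q_a)^(1/12)`,
scaling the alive-to-alive row by `1 − q_m` and sending `q_m` to death. The
matrix is rebuilt once per model year (life tables are annual; refreshing
monthly would only interpolate noise).

Surgery, fertility effects, OC side effects and outcomes other than pain
are out of scope by design.

## Accrual conventions

* **Half-cycle correction**: trapezoidal — accrual in cycle *t* uses the
  mean of the occupancy at the start and end of the cycle. Other variants
  exist; the trapezoid is the common implementation and can be switched off
  (`--no-half-cycle`) to quantify its effect (≈0.2 % of totals here).
* **Discounting**: 3.5 % a year, compounded monthly:
  `d(t) = 1.035^(−t/12)` applied to cycle *t*'s accrual. Compounding
  matches standard UK appraisal practice; simple division of the annual
  rate by 12 would differ by <0.1 % over this horizon.
* **QALYs**: annual state utilities divided by 12 per cycle.

## Cost rules (reconstruction notes)

The published analysis prints unit costs but not its accrual rules; the
rules below were chosen because together they reproduce all six published
cost/QALY cells (both arms, base case and GP-exclusion scenario) to within
0.6 %, while the more obvious readings of the unit-cost table miss some
cells by 20–30 % under any starting distribution:

* **Pain-state-only costing.** GP consultations, the OC drug and
  analgesics accrue only while the cohort is in a pain state. Clinically: a
  pain-free month generates no consultations or medication use. This
  reproduces the published GP cost components (derivable as base-case minus
  GP-exclusion totals) almost exactly.
* **GP consultations**: £26.67 per 10-minute visit, every 3 months (NHT)
  or 6 months (OC), amortised uniformly per month (cost/interval). A lumped
  mode (full visit cost in visit months, `--lumped-gp`) is provided; the
  difference is <0.1 % of totals.
* **OC drug**: £2.82 buys a pack covering three monthly cycles → £0.94 per
  cycle.
* **Analgesic ladder**: the printed paracetamol cost (£2.31/month) is the
  cost of *half* the maximum dose — exactly what the mild state uses; the
  moderate state doubles it (full maximum dose) and the severe state adds
  the full maximum ibuprofen dose (£2.43/month): 0 / 2.31 / 4.62 / 7.05 per
  month across the four alive states.

All of these are plain configuration fields, so alternative readings are
one YAML edit away.

## Starting distribution and life table

The starting split over the four alive states is not published. The default
is an equal split (0.25 each); under it the model reproduces the published
QALY totals to <0.6 %, so no calibration away from symmetry was applied.

No life table is published either. The bundled default is a Gompertz hazard
`h(age) = h0·exp(slope·(age − 30))` with `h0 = 4.5e-4`, `slope = 0.085`,
giving annual death probabilities rising from ~5e-4 at 32 to ~2.3e-3 at 50
and cumulative mortality of ~2 % over the horizon — the magnitude of UK
female period life tables, but illustrative rather than official. Any
two-column CSV (`age,q_annual`) can replace it.

## Elicitation computations

* **Counts → Beta/Dirichlet.** A row elicited as *k* movers among *n*
  hypothetical patients becomes Beta(α = k, β = n − k) for a single
  destination, or Dirichlet(stay, k₁, k₂) sampled jointly for two, so row
  sums stay exactly 1. Fractional pseudo-counts (0.1, 1.5) are accepted.
  A zero count degrades to a Fixed(0) with a warning, since Beta(0, n) is
  improper.
* **Roulette → Beta.** Method of moments at bin midpoints: histogram mean
  *m* and variance *v* give `s = m(1−m)/v − 1`, α = m·s, β = (1−m)·s. A
  single-bin histogram has zero midpoint variance; the variance is floored
  at (bin width)²/12, the within-bin uniform variance, because placing all
  chips in one bin still expresses within-bin uncertainty. The original
  elicitation used a web tool whose fitting algorithm is not published;
  method of moments is the standard, reproducible choice and recovers the
  published (α, β) means from simulated chip data.
* **Point cost → Gamma.** shape = 1/CV², scale = mean·CV², with CV = 0.2 by
  default — a conventional assumption when only a point estimate is
  published, and exposed in the config so its influence is testable.

## Probabilistic sensitivity analysis

1000 draws by default. Per draw: state utilities from their Betas (one
value per state, shared by both arms — utility is a state property);
transition rows from their Beta/Dirichlet pseudo-count distributions,
independently per arm; the GP unit cost from its Gamma (one value shared by
both arms — it is the same service) and the OC pack cost from its Gamma;
analgesic unit costs fixed. No other correlation structure is imposed —
nothing beyond the within-row Dirichlet dependence is published. Both arms
run through the cohort engine per draw; a draw that violates an engine
invariant is logged and excluded (none do under the defaults). Quadrants
classify (ΔQALY, Δcost) with the south-east defined strictly (more
effective *and* cheaper); boundary draws fall to the adjacent quadrant and
are probability-zero under continuous distributions. CEAC probabilities
compare net monetary benefit per draw, splitting exact ties equally; the
threshold grid is £0–50,000 in £1,000 steps plus a large sentinel (10⁸)
standing in for "thresholds above £50,000".

## Validation oracle

`microsim_oracle` re-implements each arm as a patient-level simulation:
individual monthly trajectories sampled from the same matrices, accruing
costs and QALYs with the same half-cycle and discounting conventions. It
shares no propagation code with the cohort engine, so agreement of cohort
totals with microsimulation means (within 3 standard errors at 200,000
patients in the acceptance suite) checks the linear-algebra path end to
end.

## Synthetic data and what passing tests show

The synthetic module generates every non-published input with known ground
truth: the Gompertz life table; multinomial one-month transition counts for
a cohort of hypothetical patients; and roulette histograms whose chips are
allocated in proportion to a known Beta's bin masses. Recovery tests fit
parameters from these and check convergence to the truth as cohort size and
chip count grow. The generators emulate an idealised, internally consistent
expert; they do not emulate real elicitation artefacts (anchoring,
overconfidence, rounding to favourite numbers), so passing recovery tests
demonstrates correctness of the fitting math, not robustness to human
biases. Likewise the life table is a smooth parametric stand-in, not an
official national table.

## Numerical choices and limitations

* Occupancy rows are checked to sum to 1 within 1e-9 every cycle; matrix
  rows within 1e-9 at build time.
* Deterministic results are reproduced to ~0.6 % rather than to the printed
  pound: the published analysis omits its life table, its starting
  distribution and its Gamma variances, so exact agreement is not
  attainable in principle. Quantities the original rounds to the pound
  (the GP-exclusion cost difference and ICER) are compared after the same
  rounding.
* Problem sizes in the test suite (e.g. 30,000-patient microsimulations in
  unit tests, 200,000 in the acceptance suite; 400–1000 PSA draws) were
  chosen so Monte-Carlo error is well below the tolerances being checked.
* The model has no treatment switching or discontinuation, no adverse
  events, and a single cohort age; these mirror the scope of the original
  analysis, not limits of the implementation.
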