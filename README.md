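# endopain

A cost-utility model comparing **oral contraceptives (OC)** against **no
hormonal treatment (NHT, pain relief only)** for endometriosis-related
pain, from an NHS England perspective. It is aimed at health economists and
HTA analysts who want a tested, scriptable implementation of this decision
problem — including the expert-elicitation computations that produced its
parameter distributions — rather than a spreadsheet.

## The model

A five-state Markov cohort model in monthly cycles. Health states are
defined on the 0–10 numerical rating scale (NRS) for pain — *no pain*
(NRS 0), *mild* (1–3), *moderate* (4–6), *severe* (7–10) — plus absorbing
all-cause death. A cohort enters at age 32 (mean age at diagnosis) and is
followed to age 50 (mean age at menopause), i.e. T = 216 cycles. Occupancy
propagates as

    x(t+1) = x(t) · P(a_t)

where the 5×5 monthly matrix `P` combines the arm's elicited pain
transitions (adjacent severity levels only) with an age-dependent monthly
death probability `1 − (1 − q_a)^(1/12)` from an annual life table; the
disease itself carries no excess mortality. Costs (GBP) and QALYs accrue on
half-cycle-corrected occupancy (trapezoid of adjacent cycle starts) and are
discounted at 3.5 % a year, compounded monthly. QALY weights per state were
elicited from a gynaecologist by the roulette (chips-and-bins) method;
transition probabilities as monthly transition counts among 1000
hypothetical patients, which also parameterise the Beta/Dirichlet
distributions of the probabilistic sensitivity analysis (PSA). Outputs are
the incremental cost-effectiveness ratio (ICER = Δcost/ΔQALY) or a
dominance verdict, a GP-cost-exclusion one-way scenario, and a 1000-draw
PSA summarised on the cost-effectiveness plane and as cost-effectiveness
acceptability curves (CEAC, via net monetary benefit λ·QALYs − cost).

Treatment costs — GP consultations (£26.67 every 3 months under NHT, every
6 months under OC), the OC drug (£2.82 per 3-cycle pack) and the analgesic
ladder (half-max paracetamol when mild, max when moderate, max paracetamol
plus max ibuprofen when severe) — accrue only while the cohort is in a pain
state; a pain-free month incurs no treatment cost. See
[docs/methods.md](docs/methods.md) for every convention and its rationale.

## Worked example

```bash
$ endopain base-case --out out/base
Base case (deterministic):
  No hormonal treatment: £1,698, 9.82 QALYs
  Oral contraceptives:  £1,107, 10.25 QALYs
  Mean difference:     £-591, 0.43 QALYs
  Verdict: oral contraceptives dominate (cheaper and more effective)
```

Over 18 years a woman under no hormonal treatment accrues about £1,698 of
discounted NHS cost and 9.82 discounted QALYs; under oral contraceptives
about £1,107 and 10.25 QALYs. OC is cheaper (the saving is driven by fewer
GP consultations) *and* more effective (the cohort drifts towards milder
pain), so it **dominates** and no ICER is reported. The same run writes
per-cycle traces and a Table-style summary CSV. Removing GP costs
(`endopain one-way-sa`) flips the cost sign: OC becomes £4 dearer for the
same 0.43 QALY gain, an ICER of ~£9 per QALY — far below any conventional
willingness-to-pay threshold.

```bash
$ endopain psa --out out/psa --draws 1000 --seed 1
PSA: 1000 draws (0 failed), SE quadrant 98.5%
CEAC: P(NHT cost-effective) at highest threshold = 0.015
```

98.5 % of parameter draws land in the south-east quadrant of the
cost-effectiveness plane (OC more effective and cheaper); the probability
that NHT is cost-effective stays ≤ 2 % even at thresholds above £50,000
per QALY. The command also writes draw-level CSVs and plane/CEAC plots.

The same pipeline is available as a library:

```python
import endopain as ep

ps = ep.load_config()                    # bundled published parameters
nht, oc, inc = ep.run_base_case(ps)
psa = ep.run_psa(ps, n_draws=1000, seed=1)
print(inc, psa.quadrant_proportions())
```

All parameters live in one YAML file (see
`src/endopain/data/default_config.yaml`); pass `--config` / `--life-table`
to override any of them, including the bundled synthetic Gompertz life
table.

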