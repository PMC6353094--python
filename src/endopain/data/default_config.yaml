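# Default parameterisation of the oral-contraceptive vs no-hormonal-treatment
# cost-effectiveness model for endometriosis-related pain (NHS perspective,
# GBP, monthly cycles, cohort aged 32 to 50).
model:
  start_age: 32
  end_age: 50
  cycle_length_months: 1
  annual_discount_rate: 0.035
  half_cycle_correction: true
  # The published model does not state the starting split; equal shares over
  # the four alive pain states is the documented default.
  initial_distribution:
    no_pain: 0.25
    mild: 0.25
    moderate: 0.25
    severe: 0.25

costs:
  gp_visit_cost: 26.67          # 10-minute GP consultation
  gp_interval_nht: 3            # months between visits, no-hormonal-treatment arm
  gp_interval_oc: 6             # months between visits, OC arm
  oc_pack_cost: 2.82            # combined OC (Microgynon), one pack
  oc_pack_cycles: 3             # cycles covered by one pack
  paracetamol_half_max_month: 2.31   # one month at half the maximum dose
  ibuprofen_max_month: 2.43          # one month at the maximum dose
  # Analgesic use scales with pain severity: mild = half the maximum
  # paracetamol dose, moderate = the full maximum dose, severe = maximum
  # paracetamol plus maximum ibuprofen.
  paracetamol_units: {no_pain: 0.0, mild: 1.0, moderate: 2.0, severe: 2.0}
  ibuprofen_units: {no_pain: 0.0, mild: 0.0, moderate: 0.0, severe: 1.0}
  # Treatment costs (GP, OC drug, analgesics) accrue only while in a pain
  # state; a pain-free month incurs no treatment cost.
  pain_states_only: true
  gp_lumped: false              # amortise GP visits per month (default) or lump at visit months
  cost_cv: 0.2                  # coefficient of variation for Gamma cost PSA

utilities:
  # Annual QALY weights per state, elicited by the roulette (chips-and-bins)
  # method; dead is 0 by construction.
  means: {no_pain: 0.905, mild: 0.802, moderate: 0.718, severe: 0.573}
  # Beta(alpha, beta) used in the probabilistic sensitivity analysis.
  beta:
    no_pain: [27.357, 3.153]
    mild: [82.023, 18.242]
    moderate: [55.931, 22.142]
    severe: [19.336, 14.487]

transitions:
  # Monthly transition probabilities between adjacent severity states,
  # elicited as transition counts among 1000 hypothetical patients per state.
  pseudo_n: 1000
  nht:
    no_pain: {mild: 0.003}
    mild: {no_pain: 0.002, moderate: 0.002}
    moderate: {mild: 0.001, severe: 0.003}
    severe: {moderate: 0.0001}
  oc:
    no_pain: {mild: 0.001}
    mild: {no_pain: 0.003, moderate: 0.0015}
    moderate: {mild: 0.003, severe: 0.0001}
    severe: {moderate: 0.004}

psa:
  draws: 1000
  seed: 2016
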