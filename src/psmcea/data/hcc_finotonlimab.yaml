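# Advanced hepatocellular carcinoma case study:
# finotonlimab + bevacizumab biosimilar (dual-agent) vs sorafenib,
# Chinese healthcare-system perspective.  All money in CNY, time in months
# unless a key says otherwise.

name: hcc_finotonlimab_vs_sorafenib

model:
  cycle_length_days: 21
  horizon_years: 10
  discount_rate_annual: 0.045
  half_cycle_correction: true
  wtp_cny_per_qaly: 299400

reference_arm: dual
comparator_arm: sorafenib

arms:
  dual:
    label: "Finotonlimab + bevacizumab biosimilar"
    pfs: {family: lognormal, params: {meanlog: 2.11975, sdlog: 0.96625}}
    os: {family: lognormal, params: {meanlog: 3.08907, sdlog: 1.09587}}
    dosing:
      components:
        - {drug: finotonlimab, mg_flat_per_cycle: 200}
        - {drug: bevacizumab, mg_per_kg_per_cycle: 15}
      duration: to_progression   # replaced by a fixed duration at calibration
  sorafenib:
    label: "Sorafenib"
    pfs: {family: lognormal, params: {meanlog: 1.573341, sdlog: 0.703413}}
    os: {family: lognormal, params: {meanlog: 2.61494, sdlog: 1.09869}}
    dosing:
      components:
        - {drug: sorafenib, mg_flat_per_cycle: 16800}  # 400 mg b.i.d. x 21 d
      duration: to_progression

utilities: {pfs: 0.76, pd: 0.68}

costs:
  unit_price_cny_per_mg:
    finotonlimab: 48.800
    bevacizumab: 10.750
    sorafenib: 0.075
  management_cny_per_cycle: 605.500
  bsc_cny_per_cycle: 6653.380
  terminal_cny: 9313.370
  weight_kg: 59.0

adverse_events:   # Grade >=3, one-time management cost at model entry
  dual:
    - {name: proteinuria, incidence: 0.065, cost_cny: 1591.000}
    - {name: platelet_count_decreased, incidence: 0.070, cost_cny: 1505.920}
    - {name: hypertension, incidence: 0.087, cost_cny: 256.200}
  sorafenib:
    - {name: palmar_plantar_erythrodysaesthesia, incidence: 0.069, cost_cny: 27.700}

sensitivity_params:   # range = plausible 95% interval; +/-20% unless published
  - {name: cost_finotonlimab_per_mg, target: price.finotonlimab,
     baseline: 48.800, min: 39.040, max: 58.560, distribution: gamma}
  - {name: cost_bevacizumab_per_mg, target: price.bevacizumab,
     baseline: 10.750, min: 8.600, max: 12.900, distribution: gamma}
  - {name: cost_sorafenib_per_mg, target: price.sorafenib,
     baseline: 0.075, min: 0.060, max: 0.090, distribution: gamma}
  - {name: cost_management_per_cycle, target: cost.management,
     baseline: 605.500, min: 484.400, max: 726.600, distribution: gamma}
  - {name: cost_bsc_per_cycle, target: cost.bsc,
     baseline: 6653.380, min: 5322.704, max: 7984.056, distribution: gamma}
  - {name: cost_terminal_care, target: cost.terminal,
     baseline: 9313.370, min: 7450.696, max: 11176.044, distribution: gamma}
  - {name: cost_ae_proteinuria, target: ae_cost.proteinuria,
     baseline: 1591.000, min: 1272.800, max: 1909.200, distribution: gamma}
  - {name: cost_ae_platelet_count_decreased, target: ae_cost.platelet_count_decreased,
     baseline: 1505.920, min: 1204.740, max: 1807.100, distribution: gamma}
  - {name: cost_ae_hypertension, target: ae_cost.hypertension,
     baseline: 256.200, min: 204.960, max: 307.440, distribution: gamma}
  - {name: cost_ae_palmar_plantar, target: ae_cost.palmar_plantar_erythrodysaesthesia,
     baseline: 27.700, min: 22.160, max: 33.240, distribution: gamma}
  - {name: incidence_proteinuria_dual, target: ae_incidence.dual.proteinuria,
     baseline: 0.065, min: 0.052, max: 0.078, distribution: beta}
  - {name: incidence_platelet_count_decreased_dual,
     target: ae_incidence.dual.platelet_count_decreased,
     baseline: 0.070, min: 0.056, max: 0.084, distribution: beta}
  - {name: incidence_hypertension_dual, target: ae_incidence.dual.hypertension,
     baseline: 0.087, min: 0.0696, max: 0.1044, distribution: beta}
  - {name: incidence_palmar_plantar_sorafenib,
     target: ae_incidence.sorafenib.palmar_plantar_erythrodysaesthesia,
     baseline: 0.069, min: 0.0552, max: 0.0828, distribution: beta}
  - {name: utility_pfs, target: utility.pfs,
     baseline: 0.760, min: 0.608, max: 0.912, distribution: beta}
  - {name: utility_pd, target: utility.pd,
     baseline: 0.680, min: 0.544, max: 0.816, distribution: beta}
  - {name: weight_kg, target: weight,
     baseline: 59.0, min: 47.2, max: 70.8, distribution: normal}
  - {name: discount_rate_annual, target: discount_rate,
     baseline: 0.045, min: 0.000, max: 0.050, distribution: scaled_beta,
     support: [0.0, 0.05]}

psa:
  n_iterations: 1000
  wtp_grid_max_cny: 1500000
  wtp_grid_step_cny: 10000

scenarios:
  horizons_years: [3, 4, 5, 6, 7, 8, 9, 10, 15]
  price_retained_fractions: [1.0, 0.7, 0.5, 0.3]
  families: [exponential, gompertz, weibull, loglogistic, lognormal]
  swept_drugs: [finotonlimab, bevacizumab]

calibration_targets:   # published base-case totals and price-sweep rows
  total_cost_cny:
    dual: 851989.07
    sorafenib: 465414.88
  incremental_cost_cny_by_retained_fraction:
    1.0: 386574.19
    0.7: 348699.50
    0.5: 323425.91
    0.3: 298152.33
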