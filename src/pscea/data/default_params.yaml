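# Default model parameters: advanced-HCC two-arm comparison for China.
# FOLFOX4 (intervention, EACH trial) vs sorafenib (comparator, ORIENTAL trial).
# Unit costs in US$; incidences are trial-period proportions.
# The sorafenib PFS median was never published and is a mandatory user input
# (survival.pfs_median left null here on purpose).

patient:
  height_cm: 161.5
  weight_kg: 61.8

utilities:
  pfs: 0.76
  pd: 0.68
  dead: 0.0

discount:
  annual_rate: 0.05
  mode: annual_compound_monthly

horizon_months: 60

intervention: folfox4
comparator: sorafenib

arms:
  folfox4:
    survival:
      os_median: 6.40
      pfs_median: 2.93
    regimen:
      cycles_per_month: 2.14        # one 48-h cycle every 14 days
      administered_inpatient: true
      components:
        - {drug: oxaliplatin,  dosing: per_m2, dose_per_admin: 85,   admins_per_cycle: 1, unit_pack: 50,   pack_cost: 290}
        - {drug: fluorouracil, dosing: per_m2, dose_per_admin: 1000, admins_per_cycle: 2, unit_pack: 400,  pack_cost: 8}
        - {drug: leucovorin,   dosing: per_m2, dose_per_admin: 200,  admins_per_cycle: 2, unit_pack: 1225, pack_cost: 16}
    schedule:
      ward_cost_per_day: 8
      ward_days_per_month: 5        # ward billed per month (see ward_per)
      test_set_cost: 155
      tests_per_month: 2.14         # once per treatment cycle
    ae_profile:
      - {name: nausea_vomiting,         cost: 65,  incidence: 0.410, group: nausea_ast_alt}
      - {name: ast_alt_abnormal,        cost: 59,  incidence: 0.317, group: nausea_ast_alt}
      - {name: alopecia,                cost: 0,   incidence: 0.0}
      - {name: anorexia,                cost: 26,  incidence: 0.268}
      - {name: bilirubin_elevated,      cost: 349, incidence: 0.202}
      - {name: fatigue,                 cost: 3,   incidence: 0.175}
      - {name: diarrhea,                cost: 13,  incidence: 0.159}
      - {name: sensory_neuropathy,      cost: 3,   incidence: 0.153}
      - {name: hfsr,                    cost: 44,  incidence: 0.0}
      - {name: rash,                    cost: 7,   incidence: 0.0}
      - {name: hypertension,            cost: 37,  incidence: 0.0}
      - {name: bone_marrow_suppression, cost: 79,  incidence: 0.689}
  sorafenib:
    survival:
      os_median: 6.5
      pfs_median: null              # not published; must be supplied by the user
    regimen:
      cycles_per_month: 1.0
      administered_inpatient: false
      components:
        - {drug: sorafenib, dosing: fixed_daily, dose_per_admin: 800, admins_per_cycle: 1, unit_pack: 12000, pack_cost: 1888}
          # 400 mg twice daily; pack of 60 x 200 mg tablets
    schedule:
      ward_cost_per_day: 0
      ward_days_per_month: 0
      test_set_cost: 155
      tests_per_month: 1.0          # once per month
    ae_profile:
      - {name: nausea_vomiting,         cost: 65,  incidence: 0.114, group: nausea_ast_alt}
      - {name: ast_alt_abnormal,        cost: 59,  incidence: 0.0,   group: nausea_ast_alt}
      - {name: alopecia,                cost: 0,   incidence: 0.248}
      - {name: anorexia,                cost: 26,  incidence: 0.128}
      - {name: bilirubin_elevated,      cost: 349, incidence: 0.0}
      - {name: fatigue,                 cost: 3,   incidence: 0.201}
      - {name: diarrhea,                cost: 13,  incidence: 0.255}
      - {name: sensory_neuropathy,      cost: 3,   incidence: 0.0}
      - {name: hfsr,                    cost: 44,  incidence: 0.050}
      - {name: rash,                    cost: 7,   incidence: 0.201}
      - {name: hypertension,            cost: 37,  incidence: 0.188}
      - {name: bone_marrow_suppression, cost: 79,  incidence: 0.0}

# Patient-perspective copayment shares per arm and cost component.
copay:
  reconciled:                        # reproduces the published patient-perspective totals
    folfox4:   {drug: 0.15, ward: 0.15, tests: 0.25, ae: 0.25}
    sorafenib: {drug: 0.25, ward: 0.15, tests: 0.25, ae: 0.25}
  literal_text:                      # the copay sentence as written (does not reproduce them)
    folfox4:   {drug: 0.25, ward: 0.15, tests: 0.15, ae: 0.25}
    sorafenib: {drug: 0.25, ward: 0.15, tests: 0.15, ae: 0.25}

thresholds:
  gdp_per_capita: 7358
  lambda_3x: 22073

# One-way ranges and PSA distributions (low <= base <= high; sd for PSA).
# distribution: normal draws are truncated (redrawn) to the valid domain,
# gamma is moment-matched (shape = (mean/sd)^2, scale = sd^2/mean),
# none = one-way only.
sensitivity:
  - {id: folfox4_survival,      target: survival_multiplier, arm: folfox4,   base: 1.0,  low: 0.8,  high: 1.2,  sd: 0.20,  distribution: normal}
  - {id: sorafenib_survival,    target: survival_multiplier, arm: sorafenib, base: 1.0,  low: 0.8,  high: 1.2,  sd: 0.20,  distribution: normal}
  - {id: sorafenib_monthly_cost, target: monthly_drug_cost,  arm: sorafenib, base: 3777, low: 3021, high: 4532, sd: 1126,  distribution: gamma}
  - {id: folfox4_monthly_cost,  target: monthly_drug_cost,   arm: folfox4,   base: 1865, low: 1492, high: 2238, sd: 373,   distribution: gamma}
  - {id: dose_oxaliplatin,      target: dose, drug: oxaliplatin,  base: 138,  low: 110,  high: 166,  sd: 28,    distribution: normal}
  - {id: dose_fluorouracil,     target: dose, drug: fluorouracil, base: 3247, low: 2597, high: 3896, sd: 649,   distribution: normal}
  - {id: dose_leucovorin,       target: dose, drug: leucovorin,   base: 649,  low: 519,  high: 779,  sd: 130,   distribution: normal}
  - {id: utility_pfs,           target: utility_pfs,              base: 0.76, low: 0.61, high: 0.91, sd: 0.152, distribution: normal}
  - {id: utility_pd,            target: utility_pd,               base: 0.68, low: 0.54, high: 0.82, sd: 0.136, distribution: normal}
  - {id: ward_monthly_cost,     target: ward_monthly_cost, arm: folfox4, base: 39, low: 19, high: 78, sd: 8,    distribution: gamma}
  - {id: ae_cost_multiplier,    target: ae_cost_multiplier,       base: 1.0,  low: 0.5,  high: 2.0,  sd: 0.20,  distribution: gamma}
  - {id: test_set_cost,         target: test_set_cost,            base: 155,  low: 78,   high: 310,  sd: 93,    distribution: gamma}
  - {id: folfox4_ward_fraction, target: hospitalized_fraction, arm: folfox4, base: 1.0, low: 0.5, high: 1.0,    distribution: none}
  - {id: discount_rate,         target: discount_rate,            base: 0.05, low: 0.0,  high: 0.08,            distribution: none}
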