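# Default model configuration: elacestrant (ELA) vs standard-of-care (SOC)
# endocrine therapy, second-/third-line HR+/HER2- advanced breast cancer,
# US payer perspective.  Costs in 2023 USD, time in months, utilities per year.
#
# The FUL arm has no published OS curve of its own; it follows the
# overall-population SOC OS curve (the only assignment consistent with the
# published FUL life-year totals in both populations).

model:
  cycle_length_months: 1.0
  horizon_cycles: 120          # 10-year horizon
  annual_discount: 0.03
  days_per_cycle: 30           # oral drugs priced per 30-day month
  eval_point: end              # {start, mid, end}; mid = half-cycle correction
  treatment_duration: until_death   # {until_progression, until_death}
  background_mortality:
    annual_prob: 0.0           # natural-mortality floor on OS; 0 = no floor

survival:
  overall:
    ELA:
      pfs: {family: lognormal, params: {meanlog: 1.414933, sdlog: 0.958343}}
      os:  {family: lognormal, params: {meanlog: 3.192779, sdlog: 0.851157}}
    SOC:
      pfs: {family: loglogistic, params: {shape: 2.24661, scale: 2.73599}}
      os:  {family: lognormal, params: {meanlog: 3.09129, sdlog: 1.09301}}
    FUL:
      pfs: {family: loglogistic, params: {shape: 2.22577, scale: 2.71317}}
      os:  {family: lognormal, params: {meanlog: 3.09129, sdlog: 1.09301}}
  esr1:
    ELA:
      pfs: {family: lognormal, params: {meanlog: 1.63382, sdlog: 1.03730}}
      os:  {family: lognormal, params: {meanlog: 3.339774, sdlog: 0.858537}}
    SOC:
      pfs: {family: loglogistic, params: {shape: 2.42158, scale: 2.57804}}
      os:  {family: lognormal, params: {meanlog: 2.982833, sdlog: 0.867711}}
    FUL:
      pfs: {family: loglogistic, params: {shape: 2.40911, scale: 2.63315}}
      os:  {family: lognormal, params: {meanlog: 3.09129, sdlog: 1.09301}}

drugs:
  ELA:
    unit_cost: 2.175           # USD per mg
    unit_size_mg: 1.0
    route: oral
    mg_per_day: 400.0
  FUL:
    unit_cost: 3.915           # USD per 25 mg
    unit_size_mg: 25.0
    route: intramuscular
    mg_per_injection: 500.0
    injections_cycle1: 2       # loading: days 1 and 15 of the first month
    injections_per_cycle: 1
  anastrozole:
    unit_cost: 0.107
    unit_size_mg: 1.0
    route: oral
    mg_per_day: 1.0
  exemestane:
    unit_cost: 0.713
    unit_size_mg: 25.0
    route: oral
    mg_per_day: 25.0
  letrozole:
    unit_cost: 0.106
    unit_size_mg: 2.5
    route: oral
    mg_per_day: 2.5

costs:                         # USD
  follow_up: 2959              # per cycle in progression-free state
  after_progression: 6549      # per cycle in progressed state
  subsequent_treatment: 9061   # per cycle in progressed state
  end_of_life: 2601            # one-time, at death
  administration: 702          # per intramuscular injection

adverse_events:                # grade 3/4 events, first model cycle only
  cost_per_event: {nausea: 2586, back_pain: 2501}
  disutility_per_year: {nausea: 0.05, back_pain: 0.07}
  risks:
    ELA: {nausea: 0.025, back_pain: 0.025}
    SOC: {nausea: 0.0090, back_pain: 0.0040}
    FUL: {back_pain: 0.0060}

utilities:                     # per year of state occupancy
  PF: 0.837
  PD: 0.443

strategies:
  ELA:
    components: [{drug: ELA, weight: 1.0}]
    ae_profile: ELA
  SOC:
    components:
      - {drug: FUL, weight: 0.6933}
      - {drug: anastrozole, weight: 0.10223333333333333}
      - {drug: letrozole, weight: 0.10223333333333333}
      - {drug: exemestane, weight: 0.10223333333333334}
    ae_profile: SOC
  FUL:
    components: [{drug: FUL, weight: 1.0}]
    ae_profile: FUL

comparisons:                   # intervention vs comparator per population
  overall: [ELA, SOC]
  esr1: [ELA, FUL]

wtp: 150000                    # USD per QALY

# One-way sensitivity-analysis ranges.  Bounds are sorted at load time
# (the FUL price bounds are published inverted).
dsa:
  - {param: drugs.ELA.unit_cost, low: 1.088, high: 2.610}
  - {param: drugs.FUL.unit_cost, low: 4.698, high: 3.132}
  - {param: drugs.anastrozole.unit_cost, low: 0.086, high: 0.128}
  - {param: drugs.exemestane.unit_cost, low: 0.571, high: 0.855}
  - {param: drugs.letrozole.unit_cost, low: 0.085, high: 0.127}
  - {param: costs.after_progression, low: 5240, high: 7859}
  - {param: costs.subsequent_treatment, low: 7248, high: 10873}
  - {param: costs.end_of_life, low: 2081, high: 3121}
  - {param: costs.follow_up, low: 2367, high: 3551}
  - {param: costs.administration, low: 561, high: 842}
  - {param: adverse_events.cost_per_event.nausea, low: 2069, high: 3103}
  - {param: adverse_events.cost_per_event.back_pain, low: 2001, high: 3001}
  - {param: adverse_events.risks.ELA.nausea, low: 0.020, high: 0.030}
  - {param: adverse_events.risks.ELA.back_pain, low: 0.020, high: 0.030}
  - {param: adverse_events.risks.SOC.nausea, low: 0.0072, high: 0.1080}
  - {param: adverse_events.risks.SOC.back_pain, low: 0.0032, high: 0.0048}
  - {param: adverse_events.risks.FUL.back_pain, low: 0.0048, high: 0.0072}
  - {param: utilities.PF, low: 0.753, high: 0.921}
  - {param: utilities.PD, low: 0.399, high: 0.487}
  - {param: adverse_events.disutility_per_year.nausea, low: 0.02, high: 0.10}
  - {param: adverse_events.disutility_per_year.back_pain, low: 0.05, high: 0.09}
  - {param: model.annual_discount, low: 0.00, high: 0.05}

psa:
  n_iterations: 1000
  utility_distribution: beta   # {beta, normal}; beta keeps utilities in [0,1]
  # parameters varied: every dsa entry except model.annual_discount;
  # costs ~ gamma, risks/utilities/disutilities ~ beta, moment-matched with
  # sd = (high - low) / (2 * 1.96)
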