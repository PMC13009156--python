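# Base-case model configuration: published input values for the PRS-guided
# CAD prevention model (2024 USD).  Distribution entries drive the PSA.
parameters:
  cad_incidence_10y_top20:
    base_value: 0.12
    units: probability
    distribution: {kind: beta, alpha: 120, beta: 880}
    source_note: "10-year CAD incidence, top 20% PRS (adult high-PRS benchmark)"
  stroke_incidence_10y_top20:
    base_value: 0.12
    units: probability
    distribution: {kind: beta, alpha: 120, beta: 880}
    source_note: "10-year stroke incidence, top 20% PRS; assumed equal to CAD"
  relative_risk_reduction:
    base_value: 0.30
    units: fraction
    distribution: {kind: lognormal-rr, median: 0.70, ci_low: 0.60, ci_high: 0.80}
    source_note: "uniform RRR of preventive intervention; RR 0.70 (95% CI 0.60-0.80)"
  utility_10_40:
    base_value: 0.95
    units: utility
    distribution: {kind: normal, mean: 0.95, sd: 0.02}
    source_note: "age-band utility weight, ages 10-40"
  utility_40_60:
    base_value: 0.92
    units: utility
    distribution: {kind: normal, mean: 0.92, sd: 0.03}
    source_note: "age-band utility weight, ages 40-60"
  utility_60plus:
    base_value: 0.85
    units: utility
    distribution: {kind: normal, mean: 0.85, sd: 0.04}
    source_note: "age-band utility weight, over 60"
  cad_fatality:
    base_value: 0.20
    units: probability
    distribution: {kind: beta, alpha: 100, beta: 400}
    source_note: "acute CAD case-fatality rate"
  stroke_fatality:
    base_value: 0.20
    units: probability
    distribution: {kind: beta, alpha: 100, beta: 400}
    source_note: "acute stroke case-fatality rate; assumed equal to CAD"
  qaly_loss_fatal_cad:
    base_value: 12.4
    units: QALY
    distribution: {kind: normal, mean: 12.4, sd: 1.2}
    source_note: "QALY loss per fatal CAD event"
  qaly_loss_fatal_stroke:
    base_value: 12.4
    units: QALY
    distribution: {kind: normal, mean: 12.4, sd: 1.2}
    source_note: "QALY loss per fatal stroke event; assumed equal to CAD"
  genetic_test_cost:
    base_value: 400
    units: USD-2024
    distribution: {kind: gamma-by-mean-cv, mean: 400, cv: 0.20}
    source_note: "one-time genetic testing + counseling + lifestyle program, per child"
  statin_monitoring_annual_cost:
    base_value: 250
    units: USD-2024/year
    distribution: {kind: gamma-by-mean-cv, mean: 250, cv: 0.20}
    source_note: "annual statin + monitoring cost, top 2% PRS children"
  lifetime_cad_cost:
    base_value: 421487
    units: USD-2024
    distribution: {kind: gamma-by-mean-cv, mean: 421487, cv: 0.25}
    source_note: "lifetime direct CAD treatment cost per case"
  lifetime_stroke_cost:
    base_value: 421487
    units: USD-2024
    distribution: {kind: gamma-by-mean-cv, mean: 421487, cv: 0.25}
    source_note: "lifetime direct stroke cost per case; assumed equal to CAD"
  discount_rate:
    base_value: 0.03
    units: rate
    distribution: {kind: fixed}
    source_note: "annual discount rate for costs and benefits"
  medical_inflation:
    base_value: 0.05
    units: rate
    distribution: {kind: fixed}
    source_note: "projected annual medical cost inflation"
  qaly_monetary_value:
    base_value: 100000
    units: USD-2024/QALY
    distribution: {kind: fixed}
    source_note: "monetary value assigned to one QALY"
  productivity_per_case:
    base_value: 200000
    units: USD-2024
    distribution: {kind: fixed}
    source_note: "productivity gain per prevented CAD case"
  cobenefit_multiplier:
    base_value: 0.15
    units: fraction
    distribution: {kind: fixed}
    source_note: "indirect health co-benefit multiplier on monetized benefits"
  qaly_gain_per_case:
    base_value: 13.3
    units: QALY
    distribution: {kind: fixed}
    source_note: "average QALYs gained per prevented CAD case"
  cohort_size:
    base_value: 10000
    units: count
    distribution: {kind: fixed}
    source_note: "children entering the model at age 10"
  high_risk_fraction:
    base_value: 0.20
    units: fraction
    distribution: {kind: fixed}
    source_note: "top PRS quintile receiving lifestyle intervention"
  very_high_risk_fraction:
    base_value: 0.02
    units: fraction
    distribution: {kind: fixed}
    source_note: "top 2% PRS additionally receiving statin therapy"
  horizon_years:
    base_value: 30
    units: year
    distribution: {kind: fixed}
    source_note: "program cost horizon for medication discounting"
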