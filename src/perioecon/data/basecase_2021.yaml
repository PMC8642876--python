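# Base-case model inputs for the smoking-cessation-therapy (SCT) vs.
# no-SCT evaluation in periodontitis, Brazilian public-health-system
# perspective, 2021 price level.  Costs are itemised in Brazilian reais
# (BRL) and converted to purchasing-power-parity US$ at 2.46 BRL per US$.
# The dsa/psa sections carry the deterministic ranges and sampling
# distributions on the PPP-US$ scale.

currency: BRL
ppp_rate: 2.46
discount_rate: 0.05
horizon_cycles: 30
cycle_length_years: 1.0
ohip_max: 56          # OHIP-14 scoring range; the instrument variant is configurable
time_rescale: hazard  # constant-hazard rescaling of multi-year probabilities
discount_effects: true
half_cycle_correction: false

probabilities:
  quit_with_sct:
    value: 0.30
    horizon_years: 1
    label: smoking cessation with therapy
  quit_without_sct:
    value: 0.07
    horizon_years: 1
    label: smoking cessation without therapy
  toothloss_nonsmokers:
    value: 0.003
    horizon_years: 1
    label: annual tooth loss in non-smokers (pooled)
  no_rehab:
    value: 0.09
    horizon_years: 1
    label: lost tooth receives no rehabilitation

relative_risks:
  former:
    point: 1.15
    log_mean: 0.14
    log_sd: 0.28
  current:
    point: 2.16     # base-case point estimate; the sensitivity rows use 2.60
    log_mean: 0.96
    log_sd: 0.27

costs:
  sct:
    items:
      - {label: "Cognitive therapy, nicotine replacement and bupropion 150 mg", amount: 559.43}
    total: 559.43
  periodontal_treatment:
    items:
      - {label: "Periodontist hourly wages (06 sessions)", amount: 200.10}
      - {label: "Scaling and root planing (06 sessions)", amount: 188.58}
      - {label: "Periapical radiographs", amount: 24.50}
      - {label: "Maintenance therapy (scaling and root planing + hourly wages)", amount: 64.78}
    total: 477.96
  maintenance_former:
    items:
      - {label: "Periodontist hourly wages (02 sessions/year)", amount: 66.70}
      - {label: "Scaling and root planing (02 sessions/year)", amount: 62.86}
    total: 129.56
  maintenance_current:
    items:
      - {label: "Periodontist hourly wages (04 sessions/year)", amount: 133.40}
      - {label: "Scaling and root planing (04 sessions/year)", amount: 125.72}
    total: 259.12
  extraction_no_rehab:
    items:
      - {label: "Dentist hourly wages (01 session)", amount: 33.35}
      - {label: "Analgesic 06/06 h for 3 days", amount: 0.60}
      - {label: "Anti-inflammatory 12/12 h for 3 days", amount: 0.36}
    total: 34.31
  extraction_partial_prosthesis:
    items:
      - {label: "Dentist hourly wages (05 sessions)", amount: 166.75}
      - {label: "Temporary prosthesis", amount: 24.14}
      - {label: "Partial removable prosthesis", amount: 150.00}
      - {label: "Panoramic radiograph", amount: 9.03}
    total: 349.92
  extraction_implant:
    items:
      - {label: "Dentist hourly wages (06 sessions)", amount: 200.10}
      - {label: "Implant", amount: 260.10}
      - {label: "Prosthesis", amount: 300.00}
      - {label: "Analgesic 06/06 h for 3 days", amount: 0.60}
      - {label: "Anti-inflammatory 12/12 h for 3 days", amount: 0.36}
      - {label: "Panoramic radiograph", amount: 9.03}
      - {label: "Periapical radiograph", amount: 3.50}
      - {label: "Cone-beam tomograph", amount: 86.75}
    total: 860.44

utilities:
  periodontitis:           {value: 0.76, low: 0.67, high: 0.89}
  after_periodontal_treatment: {value: 0.86, low: 0.76, high: 0.96}
  maintenance:             {value: 0.93, low: 0.85, high: 0.98}
  lost_no_rehab:           {value: 0.61, low: 0.55, high: 0.67}
  lost_partial_prosthesis: {value: 0.69, low: 0.62, high: 0.76}
  # No published utility exists for implant rehabilitation in this costing
  # context; this synthetic stand-in takes the upper bound of the
  # partial-prosthesis range and should be overridden when data exist.
  lost_implant:            {value: 0.76, low: 0.76, high: 0.76}

# One-way deterministic sensitivity ranges (PPP-US$ / probability scale).
dsa:
  rows:
    - {param: cost_sct, min: 185.86, base: 227.41, max: 525.59}
    # Scenario including professional-training costs; its published range
    # (271.77-611.50) sits entirely above the base-case SCT cost, so the
    # lower endpoint doubles as the row's base.
    - {param: cost_sct, min: 271.77, base: 271.77, max: 611.50, label: sct_plus_training}
    - {param: cost_periodontal, min: 174.82, base: 194.25, max: 213.68}
    - {param: cost_maintenance_current, min: 94.80, base: 105.33, max: 115.86}
    - {param: cost_maintenance_former, min: 47.39, base: 52.66, max: 57.93}
    - {param: cost_extraction_no_rehab, min: 12.56, base: 13.95, max: 15.35}
    - {param: cost_extraction_rehab, min: 128.02, base: 142.24, max: 156.46}
    - {param: discount_rate, min: 0.03, base: 0.05, max: 0.07}
    - {param: p_quit_sct, min: 0.16, base: 0.30, max: 0.38}
    # Brazilian population-based extremes; a worldwide practice-based upper
    # figure of 0.09 exists but is far outside the pooled range and is left
    # to ad-hoc scenario runs.
    - {param: p_loss_nonsmoker, min: 0.0003, base: 0.003, max: 0.006}
    - {param: p_no_rehab, min: 0.09, base: 0.09, max: 0.41}
    - {param: u_periodontitis, min: 0.67, base: 0.76, max: 0.89}
    - {param: u_after_treatment, min: 0.76, base: 0.86, max: 0.96}
    - {param: u_maintenance, min: 0.85, base: 0.93, max: 0.98}
    - {param: u_lost_no_rehab, min: 0.55, base: 0.61, max: 0.67}
    - {param: u_lost_rehab, min: 0.62, base: 0.69, max: 0.76}
    - {param: rr_former, min: 0.98, base: 1.15, max: 1.35}
    - {param: rr_current, min: 2.29, base: 2.60, max: 2.96}
    - {param: rr_current, min: 2.29, base: 2.60, max: 4.17, label: rr_current_high_intensity}

# Probabilistic sensitivity analysis: sampling distributions per parameter.
psa:
  iterations: 1000
  distributions:
    cost_sct:                  {kind: triangular, min: 185.86, mode: 227.41, max: 525.59}
    cost_periodontal:          {kind: triangular, min: 174.82, mode: 194.25, max: 213.68}
    cost_maintenance_current:  {kind: triangular, min: 94.80, mode: 105.33, max: 115.86}
    cost_maintenance_former:   {kind: triangular, min: 47.39, mode: 52.66, max: 57.93}
    cost_extraction_no_rehab:  {kind: triangular, min: 12.56, mode: 13.95, max: 15.35}
    cost_extraction_rehab:     {kind: triangular, min: 128.02, mode: 142.24, max: 156.46}
    discount_rate:             {kind: uniform, min: 0.03, max: 0.07}
    p_quit_sct:                {kind: triangular, min: 0.23, mode: 0.30, max: 0.38}
    p_loss_nonsmoker:          {kind: triangular, min: 0.0007, mode: 0.003, max: 0.0127}
    p_no_rehab:                {kind: triangular, min: 0.07, mode: 0.09, max: 0.11}
    u_periodontitis:           {kind: triangular, min: 0.67, mode: 0.76, max: 0.89}
    u_after_treatment:         {kind: triangular, min: 0.76, mode: 0.86, max: 0.96}
    u_maintenance:             {kind: triangular, min: 0.85, mode: 0.93, max: 0.98}
    u_lost_no_rehab:           {kind: triangular, min: 0.55, mode: 0.61, max: 0.67}
    u_lost_rehab:              {kind: triangular, min: 0.62, mode: 0.69, max: 0.76}
    rr_former:                 {kind: lognormal_rr, log_mean: 0.14, log_sd: 0.28}
    rr_current:                {kind: lognormal_rr, log_mean: 0.96, log_sd: 0.27}
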