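# Base-case model inputs: annual transition probabilities, colonoscopy test
# characteristics, prevention effect sizes, adverse-event probabilities,
# utility decrements, 2020-USD costs under the Japanese national fee schedule
# (converted at 106.725 JPY/USD), and economic settings.
# Any key omitted here falls back to the same packaged default.

natural_history:
  p_polyp_to_preclin_young: 0.015982   # age < 30
  p_polyp_to_preclin_old: 0.113758     # age >= 30
  age_band_cut: 30
  p_preclin_progress:
    I->II: 0.24022
    II->III: 0.22290
    III->IV: 0.27487
  p_clinical_detect:
    I: 0.07202
    II: 0.11011
    III: 0.18989
    IV: 0.87577
  # stage-specific probability of an undetected preclinical CRC already being
  # present at model entry (tuned stand-in; see docs/methods.md)
  p_preclin_at_entry:
    I: 0.0072
    II: 0.0054
    III: 0.0036
    IV: 0.0018

tests:
  sens_low_risk_polyp: 0.865     # 5-9 mm polyp
  sens_high_risk_polyp: 0.976    # 10+ mm polyp
  sens_preclinical_crc: 0.976    # not separately published; see docs/methods.md
  specificity: 1.0
  p_perforation_no_polypectomy: 0.0001

effectiveness:
  p_polyp_recur_after_idp: 0.554        # annual, 5+ mm polyps
  p_polyp_after_ipaa_lifetime: 0.036    # once in a lifetime
  rr_polyp_with_aspirin: 0.37           # 95% range 0.16-0.86
  rr_on_probability_scale: true
  recurrent_polyp_high_fraction: 0.5

adverse_events:
  p_aspirin_gi_minor: 0.04        # grade 1-2 GI symptoms, first treatment year
  p_idp_perforation: 0.004
  p_idp_bleeding: 0.023
  p_aspirin_serious_bleed: 0.0    # not published; halts aspirin when it occurs
  aspirin_gi_every_year: false

utilities:
  u_baseline: 1.0
  d_colonoscopy: 0.003
  d_colonoscopy_complication: 0.019
  d_crc_initial:    {I: 0.12, II: 0.18, III: 0.24, IV: 0.70}
  d_crc_continuing: {I: 0.05, II: 0.05, III: 0.24, IV: 0.70}
  d_ipaa: 0.110
  d_aspirin_gi: 0.004
  half_cycle_death: true

costs:
  c_colonoscopy: 145.2
  c_ipaa: 17540.0
  c_idp: 1222.5
  c_aspirin_year: 19.5
  c_crc_year1:    {I: 12367.0, II: 13109.0, III: 21929.0, IV: 25178.0}
  c_crc_year2to5: {I: 333.0,   II: 333.0,   III: 421.0,   IV: 23846.0}
  c_perforation: 12376.9
  c_bleeding: 2169.7

economics:
  discount_rate: 0.03
  wtp_threshold: 50000.0
  horizon_cycles: 40
  cohort_size: 100000
  intervention_start_age: 16
  adherence_aspirin: 1.0

fap_prevalence: 0.00006   # metadata only: the simulated cohort is all-FAP
jpy_per_usd: 106.725      # provenance of the cost conversion

psa:
  - {target: effectiveness.rr_polyp_with_aspirin, kind: beta,  base: 0.37,    range_low: 0.16,    range_high: 0.86}
  - {target: costs.c_colonoscopy,                 kind: gamma, base: 145.2,   range_low: 116.0,   range_high: 174.0}
  - {target: costs.c_ipaa,                        kind: gamma, base: 17540.0, range_low: 14032.0, range_high: 21048.0}
  - {target: costs.c_idp,                         kind: gamma, base: 1222.5,  range_low: 978.0,   range_high: 1467.0}
  - {target: costs.c_aspirin_year,                kind: gamma, base: 19.5,    range_low: 16.0,    range_high: 23.0}
  - {target: costs.c_perforation,                 kind: gamma, base: 12376.9, range_low: 9901.0,  range_high: 14852.0}
  - {target: costs.c_bleeding,                    kind: gamma, base: 2169.7,  range_low: 1736.0,  range_high: 2604.0}

owsa:
  - {target: effectiveness.rr_polyp_with_aspirin, kind: fixed, base: 0.37,    range_low: 0.16,    range_high: 0.86}
  - {target: economics.discount_rate,             kind: fixed, base: 0.03,    range_low: 0.0,     range_high: 0.04}
  - {target: economics.adherence_aspirin,         kind: fixed, base: 1.0,     range_low: 0.80,    range_high: 1.0}
  - {target: costs.c_colonoscopy,                 kind: fixed, base: 145.2,   range_low: 116.0,   range_high: 174.0}
  - {target: costs.c_ipaa,                        kind: fixed, base: 17540.0, range_low: 14032.0, range_high: 21048.0}
  - {target: costs.c_idp,                         kind: fixed, base: 1222.5,  range_low: 978.0,   range_high: 1467.0}
  - {target: costs.c_aspirin_year,                kind: fixed, base: 19.5,    range_low: 16.0,    range_high: 23.0}
  - {target: costs.c_perforation,                 kind: fixed, base: 12376.9, range_low: 9901.0,  range_high: 14852.0}
  - {target: costs.c_bleeding,                    kind: fixed, base: 2169.7,  range_low: 1736.0,  range_high: 2604.0}
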