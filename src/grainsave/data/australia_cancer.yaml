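# Australian cancer cost-of-illness inputs: pooled dose-response relative
# risks per 90 g/day of whole-grain food, the national 21 -> 48 g/day intake
# gap, AIHW direct health expenditure by category (2015-16 base year and its
# CPI Health-group 2020 equivalent), the standard uptake-scenario ladder on
# 5-year blocks, and a 7% real discount rate.
title: Australian whole-grain cancer cost-of-illness inputs

intakes:
  current: 21          # median adult whole-grain intake, g/day (content)
  target: 48           # daily target intake, g/day (content)
  product_to_content_ratio: 1.875   # 30 g product ~ 16 g whole-grain content

outcomes:
  - outcome: colorectal cancer
    condition: colorectal cancer
    rr: 0.83
    ci_lower: 0.78
    ci_upper: 0.89
    dose_g: 90
    n_studies: 6
    i_squared: 0.18
    p_heterogeneity: 0.30
  - outcome: total cancer mortality
    condition: total cancers
    rr: 0.85
    ci_lower: 0.80
    ci_upper: 0.91
    dose_g: 90
    n_studies: 6
    i_squared: 0.37
    p_heterogeneity: 0.16

scenarios:
  block_length: 5
  horizon: 20
  schedule:
    - {name: very pessimistic, uptake: 0.05, block: 0}
    - {name: pessimistic, uptake: 0.15, block: 1}
    - {name: optimistic, uptake: 0.50, block: 2}
    - {name: universal, uptake: 1.00, block: 3}

discount:
  rate: 0.07

expenditure:
  colorectal cancer:
    base: {file: crc_2015_16.csv, year: "2015-16", total: 640.3}
    current: {file: crc_2020.csv, year: "2020", total: 728.9}
  total cancers:
    base: {file: total_cancers_2015_16.csv, year: "2015-16", total: 7908.8}
    current: {file: total_cancers_2020.csv, year: "2020", total: 9002.3}

rounding:
  colorectal cancer: 2
  total cancers: 1

options:
  scaling: linear
  strict_content_units: false
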