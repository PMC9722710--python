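# Base-case inputs for the oral-contraceptive DDI burden model.
# All failure rates are annual, per 100 woman-years (Pearl index scale).
# All monetary values are direct medical costs in 2020 USD per event.
schema_version: 1

strategies:
  - name: "OC alone"
    rate_point: 0.3
  - name: "OC + enzyme inducer"
    rate_point: 2.3
    rate_low: 1.9
    rate_high: 2.8
  - name: "OC + enzyme neutral"
    rate_point: 1.6
    rate_low: 1.4
    rate_high: 1.8

# Probability that an unintended pregnancy ends in each outcome.
outcomes:
  birth: 0.492
  induced_abortion: 0.350
  spontaneous_abortion: 0.153
  ectopic_pregnancy: 0.005

# Unit costs per event: median (min-max) summaries of published payer costs.
# birth_adjusted_published is the adjusted birth cost summary as published;
# the engine's adjusted costing mode instead applies the mistimed-birth
# formula to the unadjusted birth costs (see docs/methods.md), and this
# block is retained for documentation and comparison only.
costs:
  birth:
    median: 12953
    min: 5270
    max: 28664
  induced_abortion:
    median: 940
    min: 601
    max: 4233
  spontaneous_abortion:
    median: 1121
    min: 601
    max: 3594
  ectopic_pregnancy:
    median: 6174
    min: 2840
    max: 15943
  birth_adjusted_published:
    median: 5497
    min: 2290
    max: 12453

# Mistimed-birth adjustment: a fraction f of unintended births is mistimed
# rather than unwanted; their cost is discounted back over a delay of d years
# at annual rate disc_rate, i.e. unit cost x (1 - f / (1 + disc_rate)^d).
adjustment:
  mistimed_fraction: 0.60
  discount_rate: 0.03
  delay_years: 2

settings:
  cohort_size: 1000
  cycle_length: 0.08333333333333333  # 1/12 year (one month)
  n_cycles: 12
  seed: 20211118
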