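# Base-case parameterization: PPV23 vaccination of adults >=60 in Nanning, Guangxi (2022).
# Ranged parameters are {base, low, high} mappings; a bare number means no plausible
# range is available (low = high = base).
#
# Unit conventions:
#   *_incidence / *_mortality : events per 100,000 person-years
#   natural_mortality         : deaths per 1,000 person-years
#   efficacies, coverages, wastage, serotype_coverage, discount_rate : proportions in [0, 1]
#   monetary amounts          : CNY (conversion to USD only at reporting time)

epidemiology:
  cap_incidence: {base: 38, low: 25, high: 45}      # hospitalized community-acquired pneumonia
  cap_mortality: 11.22                               # in-hospital pneumonia deaths
  men_incidence: {base: 0.21, low: 0.11, high: 0.52} # pneumococcal meningitis
  men_mortality: 0.08
  natural_mortality: 6.25                            # all-cause, per 1,000
  serotype_coverage: 0.966                           # PPV23 serotype coverage of circulating strains

vaccine:
  ve_pneumonia: {base: 0.773, low: 0.628, high: 0.918}   # single-dose efficacy vs pneumonia
  ve_meningitis: {base: 0.59, low: 0.44, high: 0.70}     # single-dose efficacy vs meningitis
  coverage_free: {base: 0.1343, low: 0.1343, high: 0.1413}
  coverage_self: {base: 0.0385, low: 0.019, high: 0.058}
  # Wastage excluded from the base case: the procurement cost decomposition is
  # reproduced with doses x price alone. The source table prints 1% (range
  # 1.3-1.68%); the upper bound is kept available for sensitivity runs.
  wastage: {base: 0.0, low: 0.0, high: 0.0168}
  ae_incidence: 0.53                                 # severe adverse events per 100,000 doses

costs:
  cap_hospitalization: {base: 10250, low: 8500, high: 12000}
  men_hospitalization: {base: 39974, low: 21836, high: 46825}
  ae_cost: {base: 7155.21, low: 5366.41, high: 8944.01}   # +/- 25% around base
  caregiver_daily: 120           # family caregiver income loss, CNY per day
  caregiver_days: 10             # caregiver days per hospitalization episode (calibration)
  vaccine_price: 166             # CNY per dose
  consumables_per_dose: 32       # cold chain + consumables, CNY per dose
  service_per_dose: 10.14        # service delivery, CNY per dose (calibration)
  cny_per_usd: 7.17              # implied by the printed 8,500 CNY <-> USD 1,185.5 pair

settings:
  discount_rate: {base: 0.03, low: 0.03, high: 0.05}
  horizon_years: 5
  cycle_years: 1
  population: 1367900            # residents aged >=60, Nanning, end of 2022
  currency_out: USD

model:
  rate_conversion: linear        # 'linear' (rate/denominator) or 'exponential' (1 - exp(-rate/denom))
  serotype_adjustment: false     # multiply efficacies by serotype_coverage when true
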