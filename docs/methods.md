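# Methods

## Model structure

A closed cohort of adults aged ≥60 is assigned to a strategy arm at t = 0
(the decision-tree layer) and then propagated through a five-state Markov
chain on 1-year cycles over a 5-year horizon — the generally accepted
duration of protection from a single PPV23 dose. States: healthy, hospitalized
community-acquired pneumonia (CAP), hospitalized pneumococcal meningitis,
pneumococcal-related death, all-cause death. Death states are absorbing;
hospital states are one-cycle tunnels: an acute episode resolves within a
cycle, so survivors return to healthy after one year. No half-cycle
correction is applied. The simulation is an expected-value cohort model:
occupancy counts are fractional and evolve as `occ(c+1) = occ(c) · P`.

Vaccination is an arm assignment at t = 0, not an event inside the chain;
efficacy is held constant over the horizon. Herd immunity, serotype
replacement and within-horizon waning are outside the model's scope: no
defensible functional form is available for them at this population and
horizon, so protection is simply constant for 5 years.

## Transition probabilities

- From healthy: P(→CAP) = cap_incidence/10⁵ × ρ, P(→meningitis) =
  men_incidence/10⁵ × ρ, P(→all-cause death) = natural_mortality/10³,
  residual mass stays healthy. ρ = 1 in the unvaccinated arm and 1 − VE in
  the vaccinated arm (optionally 1 − VE × serotype_coverage when the serotype
  switch is on; off by default, since the base-case averted-case arithmetic
  carries no serotype factor).
- Case fatality: the inputs are population-level mortality *rates*, not CFRs.
  With all fatal cases occurring in hospital, CFR = mortality rate ÷
  incidence rate (0.2953 for CAP, 0.3810 for meningitis); building a matrix
  with mortality > incidence is a hard error.
- Rate→probability conversion is direct division (38/10⁵ → 3.8×10⁻⁴). At
  these magnitudes (≤ 5×10⁻⁴/yr) the constant-hazard alternative
  1 − exp(−r) agrees to < 0.02%; it is available via
  `model.rate_conversion: exponential`. Competing exits from healthy are
  applied as independent probabilities with the residual to healthy; total
  annual exit probability is ≈ 7×10⁻³, so normalization subtleties are
  numerically negligible and are documented rather than corrected.

## Economic accounting

All internal arithmetic is in CNY; conversion to USD (÷ 7.17) happens only at
reporting time. The exchange rate is implied by the source's own printed pair
8,500 CNY ↔ USD 1,185.5.

Costs are booked at t = 0, undiscounted — a single-dose campaign at program
start: procurement `doses × (1 + wastage) × price`, consumables and service
delivery per dose, and severe adverse events at 0.53/100,000 doses ×
7,155.21 CNY. Benefits are the pneumococcal-disease costs averted: each
averted episode saves its hospitalization cost plus caregiver income loss
(120 CNY/day × `caregiver_days`), accrued as a constant annual stream over
years 1..5 and discounted with the annuity factor Σ(1+r)⁻ᵗ (4.5797 at 3%).
The annual averted-case counts are the closed form doses × incidence × VE,
which equals the first-cycle difference between equal-sized unvaccinated and
vaccinated cohorts in the Markov engine (asserted in tests); later cycles
would give slightly lower counts as the healthy pool shrinks, but the
constant-stream convention is what the base-case table arithmetic uses.
Deaths are not monetized, and adverse-event costs are only ever a cost of the
vaccinating strategy.

Decision metrics: NB = B − C, BCR = B/C (favorable iff NB > 0 ⟺ BCR > 1),
and the incremental ratio (C_a − C_b)/(B_a − B_b) between two strategies — a
monetary cost per monetary unit of disease cost averted, not a cost/QALY.
Because both B and C scale linearly with doses, strategies that differ only
in coverage have identical BCR in this model; a published table that prints
different per-arm BCRs under identical per-dose assumptions cannot be derived
from its own inputs, and this package makes no attempt to.

## Calibration choices

Three parameters the source table does not print were fixed once, by
calibration against the printed cost/benefit decomposition, and shipped as
ordinary (overridable) config values:

- `cny_per_usd = 7.17` — from the printed 8,500 CNY ↔ USD 1,185.5 pair;
- `service_per_dose = 10.14` CNY — USD 0.26 M of service delivery ÷ 183,806
  doses at 7.17;
- `caregiver_days = 10` per hospitalization episode — the 120 CNY caregiver
  figure has no stated duration; 10 days reproduces the free-arm benefit
  (USD 399,654.855) to < 0.5%.

Wastage is excluded from the base case (`wastage = 0`): the printed
procurement figure equals doses × price with no wastage multiplier. The
table's printed wastage of 1% sits outside its own printed range (1.3–1.68%);
the upper bound is kept in the config for sensitivity use, and the validator
flags any base value outside its range as a warning rather than an error.

## Sensitivity analysis

`one_way` re-runs the complete pipeline with one parameter pinned at its
lower and then upper bound, all else at base — no linear interpolation, so
the near-insensitivity of the meningitis parameters (BCR spread ≤ 0.002) is
an emergent result. `tornado` sorts entries by spread, ties broken
alphabetically. The default sweep covers the key parameters the analysis is
about — both vaccine efficacies, both hospitalization costs and the discount
rate; any list of ranged parameter paths (e.g. everything from
`iter_ranged`) can be passed instead. Incidence rates are deliberately not in
the default list: varying CAP incidence 25–45 per 100,000 changes the BCR
more than any vaccine parameter and would dominate a tornado plot meant to
compare the intervention's own levers.

Raising the discount rate from 3% to 5% lowers the BCR by the ratio of
annuity factors, ≈ 5.5% here; a much larger published figure (14.5–14.8%) is
not reproducible under any discounting convention we tried (costs at t = 0
make the BCR proportional to the annuity factor), so this package reports its
own computed value.

## Synthetic scenarios

The generator redraws every ranged parameter independently and uniformly
within its [low, high] interval — the ranges come with no distributional
information, so uniform is the honest default; a multiplicative jitter mode
(clamped to admissible domains, with warnings) is available for stress
testing. Draws follow a fixed parameter order from a single seeded
`numpy.random.Generator`, so a `ScenarioSpec` is bit-reproducible. Because
parameters are drawn independently, the cross-parameter constraint
CFR ≤ 1 can break under jitter; the generator clamps the mortality rate to
the incidence rate and warns. Deterministic stress cases (zero/full efficacy,
zero incidence, zero discounting, zero/full coverage, CFR = 1) cover the
pipeline's boundary behaviour.

What the generator emulates is parameter uncertainty around a single closed
cohort; it does not emulate age structure, secular incidence trends,
individual-level heterogeneity or transmission dynamics. Tests passing on
generated scenarios therefore demonstrate internal consistency of the
arithmetic across the plausible parameter box, not external validity of the
base-case inputs.

## Numerical conventions

- Annuity factor computed as `-expm1(-n·log1p(r))/r` to avoid cancellation
  as r → 0; r = 0 returns n exactly.
- Transition matrices are validated to row-sum 1 within 10⁻¹²; cohort
  conservation is asserted to 10⁻⁶ relative.
- Doses are kept unrounded through the pipeline (`doses_rounded` is reporting
  sugar); report serialization rounds ratios to 3 decimals and money to 2,
  never the internal values.
- BCR is undefined (error / `None`) at zero cost; the incremental ratio is
  undefined at zero benefit difference.

## Problem sizes

The base case is desk-scale: a 5×5 matrix over 5 cycles for a cohort of
1.37 M (expected values, so cohort size is just a scalar). The test suite's
brute-force path-enumeration oracle caps at 5 cycles (≤ 5⁵ paths), and
property checks use batches of 10–1,000 sampled parameter sets; everything
runs in seconds.

## Known limitations

- Single homogeneous cohort: no age bands within ≥60, no risk groups.
- Constant protection over the horizon; no waning, boosting, herd effects or
  serotype replacement.
- Benefits are purely averted treatment + caregiver costs: no QALYs/DALYs,
  no value of statistical life, no productivity losses beyond caregiver days.
- One fixed exchange rate; no inflation or cost time-trends.
- Only one-way sensitivity analysis; no probabilistic (Monte Carlo) CEA.
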