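"""Cost/benefit accounting, discounting and strategy comparison metrics.

The campaign is a single-dose program: all program costs (procurement,
consumables, service delivery, severe adverse events) are booked at t = 0
undiscounted, while benefits — pneumococcal-disease treatment and caregiver
costs averted — accrue as a constant annual stream over years 1..n and are
discounted at rate r, i.e. ``B = b_annual * sum_{t=1}^{n} (1+r)^{-t}``.

Decision metrics: net benefit ``NB = B - C``; benefit-cost ratio
``BCR = B / C`` (favorable when NB > 0, equivalently BCR > 1); and the
incremental ratio between two strategies
``ICER = (C_a - C_b) / (B_a - B_b)``, a monetary cost per monetary unit of
disease cost averted. Deaths are not monetized. All internal arithmetic is in
CNY; breakdowns convert to USD only on request.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .markov import Arm, annual_cases, build_transition_matrix, run_cohort
from .parameters import ParameterSet, per_capita_rate

__all__ = [
    "CostBreakdown",
    "BenefitBreakdown",
    "StrategyResult",
    "STRATEGIES",
    "annuity_factor",
    "doses_administered",
    "program_cost",
    "averted_annual_cases",
    "benefit_present_value",
    "net_benefit",
    "benefit_cost_ratio",
    "icer",
    "evaluate_strategy",
]

#: strategy name -> coverage parameter path ('' means no vaccination)
STRATEGIES = {
    "free": "vaccine.coverage_free",
    "self_paid": "vaccine.coverage_self",
    "no_vaccination": "",
}

DISEASES = ("CAP", "MENINGITIS")


@dataclass(frozen=True)
class CostBreakdown:
    procurement: float
    consumables: float
    service: float
    adverse_events: float
    currency: str = "CNY"

    @property
    def total(self) -> float:
        return self.procurement + self.consumables + self.service + self.adverse_events

    def convert(self, cny_per_usd: float, to: str = "USD") -> "CostBreakdown":
        if to == self.currency:
            return self
        f = 1.0 / cny_per_usd if (self.currency, to) == ("CNY", "USD") else cny_per_usd
        return replace(self, procurement=self.procurement * f, consumables=self.consumables * f,
                       service=self.service * f, adverse_events=self.adverse_events * f,
                       currency=to)


@dataclass(frozen=True)
class BenefitBreakdown:
    averted_cap_medical: float
    averted_men_medical: float
    averted_caregiver: float
    currency: str = "CNY"

    @property
    def total(self) -> float:
        return self.averted_cap_medical + self.averted_men_medical + self.averted_caregiver

    def convert(self, cny_per_usd: float, to: str = "USD") -> "BenefitBreakdown":
        if to == self.currency:
            return self
        f = 1.0 / cny_per_usd if (self.currency, to) == ("CNY", "USD") else cny_per_usd
        return replace(self, averted_cap_medical=self.averted_cap_medical * f,
                       averted_men_medical=self.averted_men_medical * f,
                       averted_caregiver=self.averted_caregiver * f, currency=to)


@dataclass(frozen=True)
class StrategyResult:
    """Discounted economics of one vaccination strategy."""

    strategy: str
    doses: float                      # unrounded population x coverage
    cost: CostBreakdown
    benefit: BenefitBreakdown
    averted_cases: dict[str, float]   # annual, by disease

    @property
    def doses_rounded(self) -> int:
        return round(self.doses)

    @property
    def net_benefit(self) -> float:
        return self.benefit.total - self.cost.total

    @property
    def bcr(self) -> float | None:
        return self.benefit.total / self.cost.total if self.cost.total > 0 else None

    def convert(self, cny_per_usd: float, to: str = "USD") -> "StrategyResult":
        return replace(self, cost=self.cost.convert(cny_per_usd, to),
                       benefit=self.benefit.convert(cny_per_usd, to))


def annuity_factor(r: float, n: int) -> float:
    """Present value of a unit annual amount over years 1..n at discount rate r."""
    if r < 0:
        raise ValueError("discount rate must be non-negative")
    if n < 1:
        raise ValueError("horizon must be at least one year")
    if r == 0:
        return float(n)
    # -expm1/log1p form avoids cancellation as r -> 0
    return -math.expm1(-n * math.log1p(r)) / r


def doses_administered(population: float, coverage: float) -> tuple[float, int]:
    """Doses given at campaign start: ``(unrounded, rounded)`` population x coverage."""
    if not 0 <= coverage <= 1:
        raise ValueError(f"coverage must be in [0, 1], got {coverage}")
    exact = population * coverage
    return exact, round(exact)


def program_cost(doses: float, p: ParameterSet) -> CostBreakdown:
    """All vaccination-program costs, incurred at t = 0 (undiscounted), in CNY.

    Procurement covers wastage via a ``doses x (1 + wastage)`` multiplier;
    severe adverse events are charged per administered dose at their incidence.
    """
    if doses < 0:
        raise ValueError("doses must be non-negative")
    c = p.costs
    return CostBreakdown(
        procurement=doses * (1.0 + p.vaccine.wastage.base) * c.vaccine_price,
        consumables=doses * c.consumables_per_dose,
        service=doses * c.service_per_dose,
        adverse_events=doses * per_capita_rate(p.vaccine.ae_incidence.base) * c.ae_cost.base,
    )


def _incidence(p: ParameterSet, disease: str) -> float:
    rv = p.epidemiology.cap_incidence if disease == "CAP" else p.epidemiology.men_incidence
    return per_capita_rate(rv.base, 100_000, p.model.rate_conversion)


def _efficacy(p: ParameterSet, disease: str) -> float:
    ve = (p.vaccine.ve_pneumonia if disease == "CAP" else p.vaccine.ve_meningitis).base
    s = p.epidemiology.serotype_coverage.base if p.model.serotype_adjustment else 1.0
    return ve * s


def averted_annual_cases(p: ParameterSet, doses: float, disease: str) -> float:
    """Expected annual hospitalizations averted among vaccinees.

    Closed form ``doses x incidence x effective efficacy``; identical to the
    first-cycle difference in incident cases between equal-sized unvaccinated
    and vaccinated cohorts from the state-transition engine.
    """
    if disease not in DISEASES:
        raise KeyError(f"unknown disease {disease!r}")
    return doses * _incidence(p, disease) * _efficacy(p, disease)


def averted_via_cohort(p: ParameterSet, doses: float, disease: str) -> float:
    """Cross-check route for :func:`averted_annual_cases` through the Markov engine."""
    cycles = p.settings.horizon_years
    traces = {
        arm: run_cohort(build_transition_matrix(p, arm), doses, cycles)
        for arm in (Arm.UNVACCINATED, Arm.VACCINATED)
    }
    diff = (annual_cases(traces[Arm.UNVACCINATED], disease)
            - annual_cases(traces[Arm.VACCINATED], disease))
    return float(diff.iloc[0])


def benefit_present_value(p: ParameterSet, averted: dict[str, float]) -> BenefitBreakdown:
    """Discounted value of disease costs averted, in CNY.

    Each averted episode saves its hospitalization cost plus caregiver income
    loss (daily rate x days per episode); the constant annual saving is
    discounted over years 1..horizon.
    """
    if any(v < 0 for v in averted.values()):
        raise ValueError("averted case counts must be non-negative")
    af = annuity_factor(p.settings.discount_rate.base, p.settings.horizon_years)
    caregiver_per_episode = p.costs.caregiver_daily * p.costs.caregiver_days
    cap = averted.get("CAP", 0.0)
    men = averted.get("MENINGITIS", 0.0)
    return BenefitBreakdown(
        averted_cap_medical=cap * p.costs.cap_hospitalization.base * af,
        averted_men_medical=men * p.costs.men_hospitalization.base * af,
        averted_caregiver=(cap + men) * caregiver_per_episode * af,
    )


def net_benefit(benefit: float, cost: float) -> float:
    """NB = B - C."""
    return benefit - cost


def benefit_cost_ratio(benefit: float, cost: float) -> float:
    """BCR = B / C; undefined for zero cost."""
    if cost == 0:
        raise ZeroDivisionError("BCR undefined for zero total cost")
    return benefit / cost


def icer(a: StrategyResult, b: StrategyResult) -> float:
    """Incremental cost per incremental monetary benefit of strategy a over b."""
    db = a.benefit.total - b.benefit.total
    if db == 0:
        raise ZeroDivisionError("ICER undefined: strategies have equal benefit")
    return (a.cost.total - b.cost.total) / db


def evaluate_strategy(p: ParameterSet, strategy: str) -> StrategyResult:
    """Run the full pipeline for one strategy arm; all amounts in CNY."""
    if strategy not in STRATEGIES:
        raise KeyError(f"unknown strategy {strategy!r}; expected one of {sorted(STRATEGIES)}")
    coverage_path = STRATEGIES[strategy]
    coverage = 0.0
    if coverage_path:
        group, _, field = coverage_path.partition(".")
        coverage = getattr(getattr(p, group), field).base
    doses, _ = doses_administered(p.settings.population, coverage)
    averted = {d: averted_annual_cases(p, doses, d) for d in DISEASES}
    return StrategyResult(
        strategy=strategy,
        doses=doses,
        cost=program_cost(doses, p),
        benefit=benefit_present_value(p, averted),
        averted_cases=averted,
    )
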