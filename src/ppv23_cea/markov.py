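"""Cohort state-transition engine over five mutually exclusive health states.

States: healthy; hospitalized community-acquired pneumonia (CAP); hospitalized
pneumococcal meningitis; pneumococcal-related death; all-cause death. The two
death states are absorbing; the two hospital states are one-cycle tunnels
(survivors of an acute episode return to healthy after one annual cycle).

Transitions are memoryless and arm-specific: in the vaccinated arm, the
healthy-to-hospital probabilities are scaled by ``1 - VE`` (optionally further
by the vaccine's serotype coverage). Case fatality inside a hospital state is
the ratio of the population mortality rate to the incidence rate for that
disease, consistent with all fatal cases occurring in hospital.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import ParameterSet, per_capita_rate

__all__ = [
    "HealthState",
    "Arm",
    "TransitionMatrix",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "annual_cases",
]

_ROW_TOL = 1e-12


class HealthState(enum.IntEnum):
    HEALTHY = 0
    HOSP_CAP = 1
    HOSP_MENINGITIS = 2
    PNEUMO_DEATH = 3
    ALL_CAUSE_DEATH = 4


#: States that can never be left once entered.
ABSORBING = (HealthState.PNEUMO_DEATH, HealthState.ALL_CAUSE_DEATH)

#: Hospital (tunnel) state per disease label.
DISEASE_STATE = {"CAP": HealthState.HOSP_CAP, "MENINGITIS": HealthState.HOSP_MENINGITIS}


class Arm(enum.Enum):
    VACCINATED = "vaccinated"
    UNVACCINATED = "unvaccinated"


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 5x5 annual transition probabilities for one arm."""

    probs: np.ndarray
    arm: Arm

    def __post_init__(self) -> None:
        m = np.asarray(self.probs, dtype=float)
        if m.shape != (len(HealthState), len(HealthState)):
            raise ValueError(f"expected a 5x5 matrix, got {m.shape}")
        if (m < -_ROW_TOL).any() or (m > 1 + _ROW_TOL).any():
            raise ValueError("transition probabilities outside [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=_ROW_TOL, rtol=0):
            raise ValueError("transition matrix rows must sum to 1")
        object.__setattr__(self, "probs", m)


@dataclass
class CohortTrace:
    """State occupancy per cycle plus per-cycle incident hospitalizations.

    ``occupancy`` is indexed by cycle 0..n (cycle 0 is the initial cohort);
    ``incident_cases`` by cycle 1..n, one column per disease. Counts are
    expected values and therefore fractional.
    """

    occupancy: pd.DataFrame
    incident_cases: pd.DataFrame
    n0: float = field(default=0.0)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format export: columns cycle, state, count, incident_cases."""
        occ = self.occupancy.reset_index().melt(
            id_vars="cycle", var_name="state", value_name="count"
        )
        inc = self.incident_cases.rename(
            columns={"CAP": HealthState.HOSP_CAP.name, "MENINGITIS": HealthState.HOSP_MENINGITIS.name}
        )
        inc = inc.reset_index().melt(id_vars="cycle", var_name="state", value_name="incident_cases")
        return occ.merge(inc, on=["cycle", "state"], how="left").fillna({"incident_cases": 0.0})


def _efficacy_reduction(p: ParameterSet, arm: Arm, ve: float) -> float:
    if arm is Arm.UNVACCINATED:
        return 1.0
    s = p.epidemiology.serotype_coverage.base if p.model.serotype_adjustment else 1.0
    return 1.0 - ve * s


def build_transition_matrix(p: ParameterSet, arm: Arm) -> TransitionMatrix:
    """Assemble the annual transition matrix for one arm of the decision tree.

    From HEALTHY, the exits are incident CAP hospitalization, incident
    meningitis hospitalization and all-cause death; the residual mass stays
    healthy. From each hospital state the cohort either dies of the disease
    (with its case-fatality ratio) or returns to HEALTHY.
    """
    epi, conv = p.epidemiology, p.model.rate_conversion
    cap_inc = per_capita_rate(epi.cap_incidence.base, 100_000, conv)
    men_inc = per_capita_rate(epi.men_incidence.base, 100_000, conv)
    natural = per_capita_rate(epi.natural_mortality.base, 1_000, conv)

    # Case fatality = mortality rate / incidence rate (both per 100,000), so the
    # conversion convention cancels; guarded against degenerate zero incidence.
    for name, inc, mort in (
        ("pneumonia", epi.cap_incidence.base, epi.cap_mortality.base),
        ("meningitis", epi.men_incidence.base, epi.men_mortality.base),
    ):
        if mort > inc:
            raise ValueError(f"{name} mortality rate exceeds incidence rate (case fatality > 1)")
    cfr_cap = epi.cap_mortality.base / epi.cap_incidence.base if epi.cap_incidence.base else 0.0
    cfr_men = epi.men_mortality.base / epi.men_incidence.base if epi.men_incidence.base else 0.0

    m = np.zeros((5, 5))
    H, C, M, PD, AD = HealthState
    m[H, C] = cap_inc * _efficacy_reduction(p, arm, p.vaccine.ve_pneumonia.base)
    m[H, M] = men_inc * _efficacy_reduction(p, arm, p.vaccine.ve_meningitis.base)
    m[H, AD] = natural
    m[H, H] = 1.0 - m[H, C] - m[H, M] - m[H, AD]
    m[C, PD] = cfr_cap
    m[C, H] = 1.0 - cfr_cap
    m[M, PD] = cfr_men
    m[M, H] = 1.0 - cfr_men
    m[PD, PD] = 1.0
    m[AD, AD] = 1.0
    return TransitionMatrix(m, arm)


def run_cohort(m: TransitionMatrix, n0: float, cycles: int) -> CohortTrace:
    """Propagate a closed cohort of ``n0`` healthy persons through ``cycles`` years.

    Occupancy evolves as ``occ(c+1) = occ(c) @ P``; incident cases in cycle
    ``c+1`` are the inflows into each hospital state during that product (the
    tunnel structure makes these equal to next-cycle occupancy, but the inflow
    is computed generally). No half-cycle correction is applied.
    """
    if n0 < 0:
        raise ValueError(f"cohort size must be non-negative, got {n0}")
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    P = m.probs
    occ = np.zeros((cycles + 1, len(HealthState)))
    occ[0, HealthState.HEALTHY] = n0
    inc = np.zeros((cycles, 2))
    hosp = [HealthState.HOSP_CAP, HealthState.HOSP_MENINGITIS]
    for c in range(cycles):
        occ[c + 1] = occ[c] @ P
        for j, state in enumerate(hosp):
            # new entries only: exclude mass already in the state that stays
            inc[c, j] = occ[c] @ P[:, state] - occ[c, state] * P[state, state]
    occupancy = pd.DataFrame(occ, columns=[s.name for s in HealthState])
    occupancy.index.name = "cycle"
    incident = pd.DataFrame(inc, columns=["CAP", "MENINGITIS"],
                            index=pd.RangeIndex(1, cycles + 1, name="cycle"))
    return CohortTrace(occupancy=occupancy, incident_cases=incident, n0=float(n0))


def annual_cases(trace: CohortTrace, disease: str) -> pd.Series:
    """Per-cycle incident hospitalized cases for ``disease`` ('CAP' or 'MENINGITIS')."""
    if disease not in DISEASE_STATE:
        raise KeyError(f"unknown disease {disease!r}; expected one of {sorted(DISEASE_STATE)}")
    return trace.incident_cases[disease]
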