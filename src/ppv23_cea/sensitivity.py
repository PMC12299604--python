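"""One-way sensitivity analysis with tornado-ordered output.

Each analysis re-runs the *full* pipeline with a single parameter pinned to
its lower and then its upper plausible bound, all other parameters held at
base — no interpolation shortcuts, so near-insensitivity (e.g. of the
meningitis parameters) is an emergent result. Outcomes are reported in the
requested metric: BCR (dimensionless) or net benefit (USD).
"""

from __future__ import annotations

from dataclasses import dataclass

from .econ import evaluate_strategy
from .parameters import ParameterSet, get_ranged, iter_ranged, set_base

__all__ = ["TornadoEntry", "KEY_PARAMETERS", "one_way", "tornado", "outcome"]

#: Parameters varied in the headline one-way analysis: the vaccine efficacies,
#: the two hospitalization costs and the discount rate. Any ranged parameter
#: path can be passed explicitly instead (see :func:`tornado`).
KEY_PARAMETERS = (
    "vaccine.ve_pneumonia",
    "vaccine.ve_meningitis",
    "costs.cap_hospitalization",
    "costs.men_hospitalization",
    "settings.discount_rate",
)

METRICS = ("BCR", "NB")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float

    @property
    def spread(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def outcome(p: ParameterSet, metric: str, strategy: str) -> float:
    """Pipeline endpoint for sensitivity runs: BCR, or net benefit in USD."""
    if metric not in METRICS:
        raise KeyError(f"unknown metric {metric!r}; expected one of {METRICS}")
    res = evaluate_strategy(p, strategy)
    if metric == "BCR":
        bcr = res.bcr
        if bcr is None:
            raise ZeroDivisionError(f"BCR undefined for zero-cost strategy {strategy!r}")
        return bcr
    return res.convert(p.costs.cny_per_usd, "USD").net_benefit


def one_way(p: ParameterSet, parameter: str, metric: str = "BCR",
            strategy: str = "free") -> TornadoEntry | None:
    """Vary one parameter across its range, everything else at base.

    Returns ``None`` for a degenerate range (low == high): nothing to vary.
    The input parameter set is never mutated.
    """
    rv = get_ranged(p, parameter)
    if not rv.has_range:
        return None
    return TornadoEntry(
        parameter=parameter,
        low_input=rv.low,
        high_input=rv.high,
        outcome_low=outcome(set_base(p, parameter, rv.low), metric, strategy),
        outcome_high=outcome(set_base(p, parameter, rv.high), metric, strategy),
    )


def tornado(p: ParameterSet, metric: str = "BCR", strategy: str = "free",
            parameters: list[str] | None = None) -> list[TornadoEntry]:
    """One-way analysis over a list of parameters, sorted by spread descending.

    ``parameters`` defaults to :data:`KEY_PARAMETERS`; pass
    ``[path for path, _ in iter_ranged(p)]`` to sweep every ranged parameter.
    Degenerate ranges are skipped; ties are broken alphabetically.
    """
    paths = KEY_PARAMETERS if parameters is None else parameters
    entries = [e for path in paths if (e := one_way(p, path, metric, strategy)) is not None]
    return sorted(entries, key=lambda e: (-e.spread, e.parameter))
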