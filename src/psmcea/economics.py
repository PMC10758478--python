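"""Cost and utility inputs: drug regimens, mixtures, adverse events.

Converts unit prices and dosing schedules into per-cycle cost streams and
turns adverse-event (AE) profiles into one-off first-cycle cost and
disutility terms.  Oral drugs are priced per day over ``days_per_cycle``
days; fulvestrant-style intramuscular regimens are priced per injection,
with a loading schedule that doubles the first model cycle and an
administration fee charged per injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DrugRegimen",
    "AdverseEventProfile",
    "StrategySpec",
    "EconomicInputs",
    "drug_cost_per_cycle",
    "ae_first_cycle_cost",
    "ae_first_cycle_disutility",
    "strategy_from_config",
    "economics_from_config",
]


@dataclass(frozen=True)
class DrugRegimen:
    """One drug: unit price plus dosing schedule.

    ``unit_cost`` is USD per ``unit_size_mg`` milligrams.  Oral drugs dose
    ``mg_per_day`` every day; intramuscular drugs give ``mg_per_injection``
    per administration, ``injections_cycle1`` times in the first cycle and
    ``injections_per_cycle`` thereafter.
    """

    name: str
    unit_cost: float
    unit_size_mg: float
    route: str  # oral | intramuscular
    mg_per_day: float = 0.0
    mg_per_injection: float = 0.0
    injections_cycle1: int = 0
    injections_per_cycle: int = 0

    def __post_init__(self):
        if self.route not in ("oral", "intramuscular"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.unit_cost < 0 or self.unit_size_mg <= 0:
            raise ValueError("unit_cost must be >= 0 and unit_size_mg > 0")

    def injections_in_cycle(self, cycle_index: int) -> int:
        if self.route != "intramuscular":
            return 0
        return self.injections_cycle1 if cycle_index == 1 else self.injections_per_cycle

    def mg_in_cycle(self, cycle_index: int, days_per_cycle: float) -> float:
        """Milligrams dispensed in the given 1-based model cycle."""
        if cycle_index < 1:
            raise ValueError("cycle_index must be >= 1")
        if self.route == "oral":
            return self.mg_per_day * days_per_cycle
        return self.mg_per_injection * self.injections_in_cycle(cycle_index)

    def acquisition_cost(self, cycle_index: int, days_per_cycle: float) -> float:
        mg = self.mg_in_cycle(cycle_index, days_per_cycle)
        return mg / self.unit_size_mg * self.unit_cost


@dataclass(frozen=True)
class AdverseEventProfile:
    """Grade-3/4 AE risks with per-event cost and annual disutility.

    Events are charged once, in the first model cycle only.
    """

    events: tuple = ()  # of (name, risk, cost_per_event, annual_disutility)

    def __post_init__(self):
        for name, risk, cost, disutil in self.events:
            if not (0.0 <= risk <= 1.0):
                raise ValueError(f"AE {name}: risk {risk} outside [0, 1]")
            if cost < 0 or disutil < 0:
                raise ValueError(f"AE {name}: negative cost or disutility")


@dataclass(frozen=True)
class StrategySpec:
    """A treatment arm: weighted drug mixture plus its AE profile."""

    name: str
    components: tuple  # of (DrugRegimen, weight)
    ae_profile: AdverseEventProfile
    admin_cost_per_injection: float = 0.0

    def __post_init__(self):
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        if any(w < 0 for _, w in self.components):
            raise ValueError("component weights must be nonnegative")


@dataclass(frozen=True)
class EconomicInputs:
    """State costs (USD per cycle unless noted) and state utilities (per year)."""

    u_pf: float
    u_pd: float
    follow_up: float
    after_progression: float
    subsequent_treatment: float
    end_of_life: float  # one-time, at death
    administration: float  # per injection

    def __post_init__(self):
        for u in (self.u_pf, self.u_pd):
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility {u} outside [0, 1]")
        for c in (self.follow_up, self.after_progression, self.subsequent_treatment,
                  self.end_of_life, self.administration):
            if c < 0:
                raise ValueError("costs must be nonnegative")


def drug_cost_per_cycle(strategy: StrategySpec, cycle_index: int,
                        days_per_cycle: float = 30.0) -> float:
    """Mixture-weighted acquisition + administration cost for one cycle.

    The administration fee applies to intramuscular components only, once per
    injection, weighted by the component's mixture share.
    """
    total = 0.0
    for regimen, weight in strategy.components:
        total += weight * regimen.acquisition_cost(cycle_index, days_per_cycle)
        total += (weight * regimen.injections_in_cycle(cycle_index)
                  * strategy.admin_cost_per_injection)
    return total


def ae_first_cycle_cost(profile: AdverseEventProfile) -> float:
    """Expected AE management cost, charged in cycle 1: sum of risk x cost."""
    return sum(risk * cost for _, risk, cost, _ in profile.events)


def ae_first_cycle_disutility(profile: AdverseEventProfile,
                              cycle_length_months: float = 1.0) -> float:
    """Expected QALY decrement in cycle 1: sum of risk x annual disutility,
    prorated to one cycle."""
    annual = sum(risk * disutil for _, risk, _, disutil in profile.events)
    return annual * cycle_length_months / 12.0


# -- construction from a model configuration -------------------------------

def _regimen_from_config(name: str, spec: dict) -> DrugRegimen:
    common = dict(name=name, unit_cost=spec["unit_cost"],
                  unit_size_mg=spec["unit_size_mg"], route=spec["route"])
    if spec["route"] == "oral":
        return DrugRegimen(**common, mg_per_day=spec["mg_per_day"])
    return DrugRegimen(
        **common,
        mg_per_injection=spec["mg_per_injection"],
        injections_cycle1=int(spec["injections_cycle1"]),
        injections_per_cycle=int(spec["injections_per_cycle"]),
    )


def _ae_profile_from_config(cfg: dict, profile_name: str) -> AdverseEventProfile:
    ae = cfg["adverse_events"]
    events = tuple(
        (event, risk, ae["cost_per_event"][event],
         ae["disutility_per_year"].get(event, 0.0))
        for event, risk in ae["risks"][profile_name].items()
    )
    return AdverseEventProfile(events)


def strategy_from_config(cfg: dict, strategy_name: str) -> StrategySpec:
    spec = cfg["strategies"][strategy_name]
    components = tuple(
        (_regimen_from_config(c["drug"], cfg["drugs"][c["drug"]]), c["weight"])
        for c in spec["components"]
    )
    return StrategySpec(
        name=strategy_name,
        components=components,
        ae_profile=_ae_profile_from_config(cfg, spec["ae_profile"]),
        admin_cost_per_injection=cfg["costs"]["administration"],
    )


def economics_from_config(cfg: dict) -> EconomicInputs:
    costs = cfg["costs"]
    return EconomicInputs(
        u_pf=cfg["utilities"]["PF"],
        u_pd=cfg["utilities"]["PD"],
        follow_up=costs["follow_up"],
        after_progression=costs["after_progression"],
        subsequent_treatment=costs["subsequent_treatment"],
        end_of_life=costs["end_of_life"],
        administration=costs["administration"],
    )
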