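"""The three-state partitioned survival model (PSM).

State occupancy at time t comes directly from the two survival curves:

    alive(t) = min(S_OS(t), S_background(t))      (mortality floor, optional)
    pf(t)    = min(S_PFS(t), alive(t))            (PFS clipped under OS)
    pd(t)    = alive(t) - pf(t)
    dead(t)  = 1 - alive(t)

Per-cycle cost, QALY and life-year increments are evaluated at a configurable
point of each cycle (start = cohort evaluation at cycle starts, mid = half-cycle
correction, end), discounted continuously-compounded per year as
(1 + r)^(-t/12) with t in months, and summed over the horizon.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .economics import (
    EconomicInputs,
    StrategySpec,
    ae_first_cycle_cost,
    ae_first_cycle_disutility,
    drug_cost_per_cycle,
)
from .survival import ParametricDistribution

__all__ = [
    "PSMConfig",
    "PSMTrace",
    "StrategyOutcome",
    "CEAResult",
    "compute_occupancy",
    "accumulate",
    "run_cea",
    "incremental",
    "psm_config_from_config",
]

logger = logging.getLogger(__name__)

EVAL_POINTS = ("start", "mid", "end")


@dataclass(frozen=True)
class PSMConfig:
    """Run-level settings of the partitioned survival model.

    cycle_length is in months; the 120-cycle default spans a 10-year horizon.
    ``background_annual_prob`` imposes a natural-mortality floor on OS
    (0 disables it).  ``treatment_duration`` decides whether drug acquisition
    is charged while progression-free only, or for as long as patients are
    alive.
    """

    cycle_length: float = 1.0
    horizon_cycles: int = 120
    annual_discount: float = 0.03
    days_per_cycle: float = 30.0
    eval_point: str = "start"
    treatment_duration: str = "until_death"
    background_annual_prob: float = 0.0

    def __post_init__(self):
        if self.eval_point not in EVAL_POINTS:
            raise ValueError(f"eval_point must be one of {EVAL_POINTS}")
        if self.treatment_duration not in ("until_progression", "until_death"):
            raise ValueError("treatment_duration must be until_progression or until_death")
        if not (0.0 <= self.annual_discount <= 1.0):
            raise ValueError("annual_discount must lie in [0, 1]")
        if self.cycle_length <= 0 or self.horizon_cycles < 1 or self.days_per_cycle <= 0:
            raise ValueError("cycle_length, horizon_cycles, days_per_cycle must be positive")

    @property
    def eval_offset(self) -> float:
        """Within-cycle evaluation offset in cycle units."""
        return {"start": 0.0, "mid": 0.5, "end": 1.0}[self.eval_point]

    def discount_factor(self, t_months):
        return (1.0 + self.annual_discount) ** (-np.asarray(t_months, dtype=float) / 12.0)


@dataclass
class PSMTrace:
    """Per-cycle occupancy and discounted increments, as a DataFrame.

    ``table`` has one row per cycle (1-based) with columns: t_eval (months),
    pf, pd, dead (occupancy at t_eval), incident_death (per-cycle increase of
    the dead compartment between cycle boundaries), and — once accumulated —
    cost, qaly, ly (discounted increments).
    """

    table: pd.DataFrame
    clipped_cycles: int = 0  # cycles where S_PFS exceeded (clipped) alive


def _occupancy_at(pfs: ParametricDistribution, os: ParametricDistribution,
                  cfg: PSMConfig, t_months: np.ndarray):
    s_os = np.asarray(os.sf(t_months), dtype=float)
    if cfg.background_annual_prob > 0.0:
        s_bg = (1.0 - cfg.background_annual_prob) ** (t_months / 12.0)
        s_os = np.minimum(s_os, s_bg)
    s_pfs = np.asarray(pfs.sf(t_months), dtype=float)
    pf = np.minimum(s_pfs, s_os)
    clipped = int(np.sum(s_pfs > s_os + 1e-15))
    return pf, s_os, clipped


def compute_occupancy(pfs: ParametricDistribution, os: ParametricDistribution,
                      cfg: PSMConfig) -> PSMTrace:
    """Evaluate state occupancy for every cycle of the horizon.

    Occupancy is evaluated at each cycle's ``eval_point``; incident deaths
    (for one-time end-of-life cost) are always the increase of the dead
    compartment between consecutive cycle boundaries.
    """
    cycles = np.arange(1, cfg.horizon_cycles + 1)
    t_eval = (cycles - 1 + cfg.eval_offset) * cfg.cycle_length
    pf, alive, clipped = _occupancy_at(pfs, os, cfg, t_eval)

    bounds = np.arange(0, cfg.horizon_cycles + 1) * cfg.cycle_length
    _, alive_b, _ = _occupancy_at(pfs, os, cfg, bounds)
    incident_death = -np.diff(alive_b)  # dead(k) - dead(k-1) >= 0 up to rounding

    if clipped:
        logger.warning("PFS curve exceeded OS in %d of %d cycles; clipped",
                       clipped, cfg.horizon_cycles)
    table = pd.DataFrame({
        "cycle": cycles,
        "t_eval": t_eval,
        "pf": pf,
        "pd": alive - pf,
        "dead": 1.0 - alive,
        "incident_death": np.maximum(incident_death, 0.0),
    })
    return PSMTrace(table=table, clipped_cycles=clipped)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one strategy."""

    strategy: str
    total_cost: float
    total_qalys: float
    total_lys: float
    trace: PSMTrace = field(repr=False, compare=False, default=None)


@dataclass(frozen=True)
class CEAResult:
    """Per-strategy totals plus the pairwise incremental comparison."""

    population: str
    outcomes: dict  # name -> StrategyOutcome
    intervention: str
    comparator: str
    incr_cost: float
    incr_qalys: float
    incr_lys: float
    icer: float  # USD/QALY; nan when undefined, -inf marks dominance
    dominance: str  # "", "intervention dominates", "comparator dominates", "undefined"


def accumulate(trace: PSMTrace, strategy: StrategySpec, econ: EconomicInputs,
               cfg: PSMConfig) -> StrategyOutcome:
    """Attach discounted cost/QALY/LY increments to a trace and total them.

    Per cycle: progression-free patients accrue drug (under either duration
    mode) plus follow-up cost and u_PF; progressed patients accrue
    after-progression plus subsequent-treatment cost (plus drug when
    treatment runs until death) and u_PD; incident deaths accrue the one-time
    end-of-life cost; expected AE cost and disutility are charged in cycle 1.
    """
    tab = trace.table
    cycles = tab["cycle"].to_numpy()
    pf = tab["pf"].to_numpy()
    pd_ = tab["pd"].to_numpy()
    alive = pf + pd_
    df = cfg.discount_factor(tab["t_eval"].to_numpy())
    years_per_cycle = cfg.cycle_length / 12.0

    drug = np.array([drug_cost_per_cycle(strategy, int(c), cfg.days_per_cycle)
                     for c in cycles])
    drug_occ = pf if cfg.treatment_duration == "until_progression" else alive

    cost = (drug * drug_occ
            + pf * econ.follow_up
            + pd_ * (econ.after_progression + econ.subsequent_treatment)
            + tab["incident_death"].to_numpy() * econ.end_of_life)
    qaly = (pf * econ.u_pf + pd_ * econ.u_pd) * years_per_cycle
    ly = alive * years_per_cycle

    ae_cost = ae_first_cycle_cost(strategy.ae_profile)
    ae_dis = ae_first_cycle_disutility(strategy.ae_profile, cfg.cycle_length)
    cost = cost + np.where(cycles == 1, ae_cost, 0.0)
    qaly = qaly - np.where(cycles == 1, ae_dis, 0.0)

    out = tab.copy()
    out["cost"] = cost * df
    out["qaly"] = qaly * df
    out["ly"] = ly * df
    return StrategyOutcome(
        strategy=strategy.name,
        total_cost=float(out["cost"].sum()),
        total_qalys=float(out["qaly"].sum()),
        total_lys=float(out["ly"].sum()),
        trace=PSMTrace(table=out, clipped_cycles=trace.clipped_cycles),
    )


def incremental(intervention: StrategyOutcome, comparator: StrategyOutcome):
    """Incremental cost, QALYs, LYs and the ICER (with dominance handling)."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qalys - comparator.total_qalys
    d_ly = intervention.total_lys - comparator.total_lys
    dominance = ""
    if d_qaly == 0.0:
        icer = math.nan
        dominance = "undefined" if d_cost == 0.0 else (
            "comparator dominates" if d_cost > 0 else "intervention dominates")
    elif d_qaly > 0 and d_cost <= 0:
        icer = d_cost / d_qaly
        dominance = "intervention dominates"
    elif d_qaly < 0 and d_cost >= 0:
        icer = d_cost / d_qaly
        dominance = "comparator dominates"
    else:
        icer = d_cost / d_qaly
    return d_cost, d_qaly, d_ly, icer, dominance


def psm_config_from_config(cfg: dict) -> PSMConfig:
    m = cfg["model"]
    return PSMConfig(
        cycle_length=m["cycle_length_months"],
        horizon_cycles=m["horizon_cycles"],
        annual_discount=m["annual_discount"],
        days_per_cycle=m["days_per_cycle"],
        eval_point=m["eval_point"],
        treatment_duration=m["treatment_duration"],
        background_annual_prob=m["background_mortality"].get("annual_prob", 0.0),
    )


def run_cea(cfg: dict, population: str, strategies: Sequence[str] | None = None,
            keep_traces: bool = False) -> CEAResult:
    """Run the full model for one population.

    ``strategies`` defaults to every strategy with curves for the population;
    the incremental comparison pairs the configured intervention vs
    comparator for that population.
    """
    from .config import distribution_from_config
    from .economics import economics_from_config, strategy_from_config

    if population not in cfg["survival"]:
        raise ValueError(f"unknown population {population!r}")
    psm = psm_config_from_config(cfg)
    econ = economics_from_config(cfg)
    pair = cfg["comparisons"][population]
    if strategies is None:
        strategies = [s for s in cfg["strategies"] if s in cfg["survival"][population]]

    outcomes = {}
    for name in strategies:
        curves = cfg["survival"][population][name]
        pfs = distribution_from_config(curves["pfs"], f"survival.{population}.{name}.pfs")
        os_ = distribution_from_config(curves["os"], f"survival.{population}.{name}.os")
        trace = compute_occupancy(pfs, os_, psm)
        outcome = accumulate(trace, strategy_from_config(cfg, name), econ, psm)
        if not keep_traces:
            outcome = StrategyOutcome(outcome.strategy, outcome.total_cost,
                                      outcome.total_qalys, outcome.total_lys, None)
        outcomes[name] = outcome

    d_cost, d_qaly, d_ly, icer, dominance = incremental(
        outcomes[pair[0]], outcomes[pair[1]])
    return CEAResult(
        population=population,
        outcomes=outcomes,
        intervention=pair[0],
        comparator=pair[1],
        incr_cost=d_cost,
        incr_qalys=d_qaly,
        incr_lys=d_ly,
        icer=icer,
        dominance=dominance,
    )
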