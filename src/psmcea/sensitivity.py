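"""Deterministic and probabilistic sensitivity analysis.

One-way DSA re-runs the full model with each parameter at its low/high bound
(everything else at base) and reports tornado entries sorted by ICER spread.
PSA draws all uncertain parameters jointly — costs from gamma, probabilities
and utilities from beta (optionally normal), hyper-parameters moment-matched
to the base value and range (sd = (high - low) / (2 * 1.96)) — re-evaluates
the model per draw, and summarizes the draws as an incremental scatter and a
cost-effectiveness acceptability curve (CEAC) over a willingness-to-pay
(WTP) grid, using net monetary benefit NMB = WTP * QALY - cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import get_param, set_param
from .engine import run_cea

__all__ = [
    "DSASpec",
    "TornadoEntry",
    "PSASampleSet",
    "dsa_specs_from_config",
    "one_way_dsa",
    "draw_psa_parameters",
    "run_psa",
    "tornado_table",
]

logger = logging.getLogger(__name__)

DEFAULT_WTP_GRID = np.arange(0, 500_001, 10_000)

#: config sections whose parameters are cost-like (gamma in PSA); everything
#: else varied in PSA is a probability or utility (beta).
_COST_PREFIXES = ("drugs.", "costs.", "adverse_events.cost_per_event.")


@dataclass(frozen=True)
class DSASpec:
    """One-way range for a dotted parameter id; bounds sorted at creation."""

    param: str
    low: float
    high: float

    def __post_init__(self):
        lo, hi = sorted((float(self.low), float(self.high)))
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)


@dataclass(frozen=True)
class TornadoEntry:
    param: str
    low: float
    high: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def dsa_specs_from_config(cfg: dict) -> list:
    specs = [DSASpec(e["param"], e["low"], e["high"]) for e in cfg.get("dsa", [])]
    for spec in specs:
        base = get_param(cfg, spec.param)
        if not (spec.low <= base <= spec.high):
            raise ValueError(f"{spec.param}: base {base} outside [{spec.low}, {spec.high}]")
    return specs


def one_way_dsa(cfg: dict, population: str, specs=None) -> list:
    """Tornado entries for one population, sorted by ICER spread descending."""
    if specs is None:
        specs = dsa_specs_from_config(cfg)
    entries = []
    for spec in specs:
        get_param(cfg, spec.param)  # raises on unknown id
        icers = []
        for bound in (spec.low, spec.high):
            result = run_cea(set_param(cfg, spec.param, bound), population)
            icers.append(result.icer)
        entries.append(TornadoEntry(spec.param, spec.low, spec.high, *icers))
    return sorted(entries, key=lambda e: e.spread, reverse=True)


def tornado_table(entries) -> pd.DataFrame:
    return pd.DataFrame(
        [{"param": e.param, "low": e.low, "high": e.high,
          "icer_at_low": e.icer_at_low, "icer_at_high": e.icer_at_high,
          "spread": e.spread} for e in entries]
    )


# -- probabilistic sensitivity analysis ------------------------------------


def _moment_matched_gamma(base, sd, rng):
    if sd == 0 or base == 0:
        return base
    shape = (base / sd) ** 2
    scale = sd**2 / base
    return rng.gamma(shape, scale)


def _moment_matched_beta(base, sd, low, high, rng, param=""):
    if sd == 0:
        return base
    var = sd**2
    if var >= base * (1.0 - base) or base <= 0 or base >= 1:
        # infeasible moment match: fall back to a beta fitted over the range
        logger.warning("%s: beta moment match infeasible (base=%.4g sd=%.4g); "
                       "using range-fitted beta", param, base, sd)
        span = max(high - low, 1e-12)
        mean = (base - low) / span
        a = max(mean * 4.0, 1e-3)
        b = max((1.0 - mean) * 4.0, 1e-3)
        return low + span * rng.beta(a, b)
    nu = base * (1.0 - base) / var - 1.0
    return rng.beta(base * nu, (1.0 - base) * nu)


def draw_psa_parameters(cfg: dict, rng: np.random.Generator,
                        specs=None, sd_scale: float = 1.0) -> dict:
    """One joint draw: dotted parameter id -> sampled value.

    Cost-like parameters are gamma, probabilities/utilities beta (or normal,
    clipped to [0, 1], when ``psa.utility_distribution`` is ``normal``); the
    discount rate is excluded (a policy choice, not a sampling uncertainty).
    ``sd_scale`` shrinks every sd (for convergence-to-base checks).
    """
    if specs is None:
        specs = dsa_specs_from_config(cfg)
    use_normal = cfg.get("psa", {}).get("utility_distribution", "beta") == "normal"
    draw = {}
    for spec in specs:
        if spec.param == "model.annual_discount":
            continue
        base = float(get_param(cfg, spec.param))
        sd = (spec.high - spec.low) / (2.0 * 1.96) * sd_scale
        if spec.param.startswith(_COST_PREFIXES):
            value = _moment_matched_gamma(base, sd, rng)
        elif use_normal:
            value = float(np.clip(rng.normal(base, sd), 0.0, 1.0))
        else:
            value = _moment_matched_beta(base, sd, spec.low, spec.high, rng, spec.param)
        draw[spec.param] = float(max(value, 0.0))
    return draw


@dataclass
class PSASampleSet:
    """Seeded PSA output: per-draw outcomes, scatter, and CEAC."""

    population: str
    seed: int
    n_iterations: int
    strategies: tuple
    intervention: str
    comparator: str
    draws: pd.DataFrame = field(repr=False)     # one row per draw: params + outcomes
    wtp_grid: np.ndarray = field(repr=False)
    ceac: pd.DataFrame = field(repr=False)      # columns: wtp, P(strategy) ...

    def prob_cost_effective(self, wtp: float, strategy: str | None = None) -> float:
        """Fraction of draws where the strategy has the highest NMB at wtp."""
        strategy = strategy or self.intervention
        nmb = {s: wtp * self.draws[f"qalys_{s}"] - self.draws[f"cost_{s}"]
               for s in self.strategies}
        others = [nmb[s] for s in self.strategies if s != strategy]
        wins = nmb[strategy].to_numpy() > np.max(np.column_stack(others), axis=1)
        return float(np.mean(wins))


def run_psa(cfg: dict, population: str, n: int | None = None,
            seed: int = 0, wtp_grid=None, sd_scale: float = 1.0) -> PSASampleSet:
    """Second-order Monte Carlo over the uncertain parameters.

    Survival-curve parameters are held fixed (no published uncertainty for
    them); each draw re-runs the full economic model.  Ties in the NMB
    comparison count for the comparator, so CEAC probabilities across the
    compared strategies sum to exactly 1 at every WTP.
    """
    n = n if n is not None else cfg.get("psa", {}).get("n_iterations", 1000)
    wtp_grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid)
    rng = np.random.default_rng(seed)
    specs = dsa_specs_from_config(cfg)
    pair = tuple(cfg["comparisons"][population])
    strategies = [s for s in cfg["strategies"] if s in cfg["survival"][population]]

    rows = []
    for _ in range(n):
        draw = draw_psa_parameters(cfg, rng, specs=specs, sd_scale=sd_scale)
        cfg_i = cfg
        for dotted, value in draw.items():
            cfg_i = set_param(cfg_i, dotted, value)
        result = run_cea(cfg_i, population, strategies=strategies)
        row = dict(draw)
        for name, outcome in result.outcomes.items():
            row[f"cost_{name}"] = outcome.total_cost
            row[f"qalys_{name}"] = outcome.total_qalys
        row["incr_cost"] = result.incr_cost
        row["incr_qalys"] = result.incr_qalys
        rows.append(row)
    draws = pd.DataFrame(rows)

    # CEAC restricted to the compared pair; ties go to the comparator
    qi = draws[f"qalys_{pair[0]}"].to_numpy()
    ci = draws[f"cost_{pair[0]}"].to_numpy()
    qc = draws[f"qalys_{pair[1]}"].to_numpy()
    cc = draws[f"cost_{pair[1]}"].to_numpy()
    ceac_rows = []
    for wtp in wtp_grid:
        wins = (wtp * qi - ci) > (wtp * qc - cc)
        p = float(np.mean(wins))
        ceac_rows.append({"wtp": float(wtp), pair[0]: p, pair[1]: 1.0 - p})
    ceac = pd.DataFrame(ceac_rows)

    return PSASampleSet(
        population=population, seed=seed, n_iterations=n,
        strategies=tuple(pair), intervention=pair[0], comparator=pair[1],
        draws=draws, wtp_grid=wtp_grid, ceac=ceac,
    )
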