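"""Synthetic digitized Kaplan-Meier curves from known distributions.

Stands in for manually digitized survival figures: draws event times from a
known parametric truth, applies a censoring mechanism, computes the exact KM
estimator, samples it on a digitization grid with optional jitter (isotonic
repair keeps the jittered curve a valid survival function), and emits the
matching number-at-risk table.  The hidden individual-patient truth is
returned alongside, so reconstruction and fitting can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .config import default_config
from .reconstruct import DigitizedCurve, ReconstructedIPD, RiskTable
from .survival import ParametricDistribution

__all__ = ["SyntheticCurveSpec", "simulate_km", "make_reference_config",
           "write_curve_csv", "write_risk_csv"]


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Recipe for one synthetic digitized curve.

    censoring_mechanism ``uniform`` censors a random fraction
    (``censoring_rate``) of subjects at a uniform time before their event;
    ``admin`` censors everyone still at risk at ``admin_cutoff`` months.
    ``grid_step`` is the digitization spacing in months and ``jitter_sd`` the
    standard deviation of additive digitizer noise on the survival axis.
    """

    true_dist: ParametricDistribution
    n_subjects: int
    censoring_mechanism: str = "uniform"  # uniform | admin
    censoring_rate: float = 0.0
    admin_cutoff: float = np.inf
    grid_step: float = 1.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be >= 10")
        if self.jitter_sd < 0 or self.grid_step <= 0:
            raise ValueError("jitter_sd must be >= 0 and grid_step > 0")
        if self.censoring_mechanism not in ("uniform", "admin"):
            raise ValueError("censoring_mechanism must be uniform or admin")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")


def _isotonic_repair(s: np.ndarray) -> np.ndarray:
    """Clip to [0, 1], force S(0)=1 and nonincreasing (running minimum)."""
    s = np.clip(s, 0.0, 1.0)
    s[0] = 1.0
    return np.minimum.accumulate(s)


def simulate_km(spec: SyntheticCurveSpec):
    """Generate (DigitizedCurve, RiskTable, truth ReconstructedIPD)."""
    rng = np.random.default_rng(spec.seed)
    event_times = spec.true_dist.rvs(spec.n_subjects, rng)

    times = np.asarray(event_times, dtype=float)
    events = np.ones(spec.n_subjects, dtype=int)
    if spec.censoring_mechanism == "uniform" and spec.censoring_rate > 0:
        censored = rng.random(spec.n_subjects) < spec.censoring_rate
        ctimes = rng.uniform(0.0, np.where(np.isfinite(times), times, 1.0))
        times = np.where(censored, ctimes, times)
        events = np.where(censored, 0, events)
    cutoff = spec.admin_cutoff if np.isfinite(spec.admin_cutoff) else None
    if cutoff is None and not np.all(np.isfinite(times)):
        cutoff = float(np.max(times[np.isfinite(times)])) + 1.0
    if cutoff is not None:
        over = times > cutoff
        times = np.where(over, cutoff, times)
        events = np.where(over, 0, events)

    truth = ReconstructedIPD(tuple(zip(times, events)))

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = np.arange(0.0, float(np.max(times)) + spec.grid_step, spec.grid_step)
    if grid[0] > 0:
        grid = np.insert(grid, 0, 0.0)
    s_grid = kmf.survival_function_at_times(grid).to_numpy()
    if np.all(s_grid[1:] < 1e-12):
        raise ValueError("all subjects failed or were censored before the first grid point")
    if spec.jitter_sd > 0:
        s_grid = s_grid + rng.normal(0.0, spec.jitter_sd, size=len(s_grid))
    s_grid = _isotonic_repair(s_grid)

    n_risk = np.array([int(np.sum(times >= g)) for g in grid])
    keep = n_risk > 0
    keep[0] = True
    curve = DigitizedCurve(tuple(zip(grid[keep], s_grid[keep])))
    risk = RiskTable(tuple(zip(grid[keep], n_risk[keep])))
    return curve, risk, truth


def make_reference_config() -> dict:
    """The bundled default model configuration (every published model input:
    survival parameters, unit costs, dosing, AE profiles, utilities,
    sensitivity ranges), validated."""
    return default_config()


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    pd.DataFrame(curve.points, columns=["time", "survival"]).to_csv(path, index=False)


def write_risk_csv(risk: RiskTable, path) -> None:
    pd.DataFrame(risk.intervals, columns=["time", "n_risk"]).to_csv(path, index=False)
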