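"""Parametric survival distributions used for extrapolation.

Five families are supported, under the standard survival-analysis
parameterizations (time is always in months):

========== =================== ==============================================
family      parameters          survival function S(t)
========== =================== ==============================================
weibull     shape a, scale b    exp(-(t/b)^a)
loglogistic shape a, scale b    1 / (1 + (t/b)^a)
lognormal   meanlog mu,         1 - Phi((ln t - mu) / sigma)
            sdlog sigma
gompertz    shape a, rate b     exp(-(b/a)(e^{a t} - 1));  a -> 0 gives the
                                exponential with rate b
gamma       shape a, scale b    1 - GammaInc(a, t/b)   (regularized)
========== =================== ==============================================

These conventions make the parameter names printed in model configuration
files unambiguous: e.g. a lognormal median is exp(meanlog), a log-logistic
median is its scale.  Weibull, log-logistic, log-normal and gamma are backed
by frozen ``scipy.stats`` distributions; Gompertz is closed-form in-package
because its shape parameter may be arbitrarily small (or negative, giving an
improper distribution with a surviving fraction), which the scipy
parameterization cannot represent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ParametricDistribution",
    "survival",
    "median",
    "mean_survival",
]

FAMILIES = ("weibull", "loglogistic", "lognormal", "gompertz", "gamma")

#: Parameter-vector names per family, in canonical order.
PARAM_NAMES = {
    "weibull": ("shape", "scale"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gompertz": ("shape", "rate"),
    "gamma": ("shape", "scale"),
}

# Domain constraints: parameter -> must be strictly positive?  The Gompertz
# shape is the single unconstrained parameter (negative shape = decelerating
# hazard with a cure fraction).
_POSITIVE = {
    "weibull": ("shape", "scale"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("sdlog",),
    "gompertz": ("rate",),
    "gamma": ("shape", "scale"),
}


@dataclass(frozen=True)
class ParametricDistribution:
    """A survival distribution: one of five families plus its parameters.

    Parameters
    ----------
    family
        One of :data:`FAMILIES`.
    params
        Named parameter mapping, e.g. ``{"meanlog": 1.41, "sdlog": 0.96}``.
        Names must match :data:`PARAM_NAMES` for the family exactly.

    Time is in months throughout.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        expected = set(PARAM_NAMES[self.family])
        got = set(self.params)
        if got != expected:
            raise ValueError(
                f"{self.family} expects parameters {sorted(expected)}, got {sorted(got)}"
            )
        for name, value in self.params.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.family}.{name} must be finite, got {value}")
            if name in _POSITIVE[self.family] and value <= 0:
                raise ValueError(f"{self.family}.{name} must be > 0, got {value}")
        object.__setattr__(self, "params", dict(self.params))

    # -- internal ----------------------------------------------------------

    def _frozen(self):
        """The scipy frozen distribution for the four scipy-backed families."""
        p = self.params
        if self.family == "weibull":
            return stats.weibull_min(p["shape"], scale=p["scale"])
        if self.family == "loglogistic":
            return stats.fisk(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(p["sdlog"], scale=math.exp(p["meanlog"]))
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        raise AssertionError(self.family)

    @staticmethod
    def _check_t(t):
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("t must be finite")
        if np.any(t < 0):
            raise ValueError("t must be >= 0")
        return t

    def _gompertz_cumhaz(self, t):
        a, b = self.params["shape"], self.params["rate"]
        if a == 0.0:
            return b * t
        # H(t) = (b/a)(e^{at}-1); expm1 keeps the a->0 exponential limit exact
        with np.errstate(over="ignore"):
            return b * np.expm1(a * t) / a

    # -- public surface ----------------------------------------------------

    def sf(self, t):
        """Survival function S(t); vectorized over t >= 0."""
        t = self._check_t(t)
        if self.family == "gompertz":
            out = np.exp(-self._gompertz_cumhaz(t))
        else:
            out = self._frozen().sf(t)
        return out if out.shape else float(out)

    def pdf(self, t):
        t = self._check_t(t)
        if self.family == "gompertz":
            out = np.exp(self.logpdf(t))
        else:
            out = self._frozen().pdf(t)
        return out if out.shape else float(out)

    def logpdf(self, t):
        t = self._check_t(t)
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            out = np.log(b) + a * t - self._gompertz_cumhaz(t)
        else:
            out = self._frozen().logpdf(t)
        return out if out.shape else float(out)

    def logsf(self, t):
        t = self._check_t(t)
        if self.family == "gompertz":
            out = -self._gompertz_cumhaz(t)
        else:
            out = self._frozen().logsf(t)
        return out if out.shape else float(out)

    def hazard(self, t):
        """Instantaneous hazard h(t) = f(t)/S(t)."""
        t = self._check_t(t)
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            out = b * np.exp(a * t)
            return out if out.shape else float(out)
        return np.exp(self.logpdf(t) - self.logsf(t))

    def median(self) -> float:
        """Time m with S(m) = 1/2, closed-form where available.

        A negative-shape Gompertz whose surviving fraction exceeds 1/2 has no
        median; ``inf`` is returned.
        """
        p = self.params
        if self.family == "lognormal":
            return math.exp(p["meanlog"])
        if self.family == "loglogistic":
            return p["scale"]
        if self.family == "weibull":
            return p["scale"] * math.log(2.0) ** (1.0 / p["shape"])
        if self.family == "gompertz":
            a, b = p["shape"], p["rate"]
            if a == 0:
                return math.log(2.0) / b
            arg = 1.0 + a * math.log(2.0) / b
            if arg <= 0:  # cure fraction above 1/2
                return math.inf
            return math.log(arg) / a
        return float(self._frozen().median())

    def rvs(self, size: int, rng: np.random.Generator):
        """Draw event times (inverse-CDF sampling for Gompertz)."""
        if self.family == "gompertz":
            a, b = self.params["shape"], self.params["rate"]
            u = rng.uniform(size=size)
            # invert S(t)=u: t = ln(1 - a ln(u)/b)/a  (a->0: -ln(u)/b)
            if a == 0:
                return -np.log(u) / b
            arg = 1.0 - a * np.log(u) / b
            with np.errstate(invalid="ignore"):
                t = np.log(arg) / a
            # improper tail (negative shape): survivors never fail; represent
            # as +inf event times — callers censor administratively
            t[~np.isfinite(t) | (arg <= 0)] = np.inf
            return t
        return self._frozen().rvs(size=size, random_state=rng)

    def param_vector(self) -> np.ndarray:
        return np.array([self.params[k] for k in PARAM_NAMES[self.family]])


# Functional aliases matching the operation names of the public contract.

def survival(dist: ParametricDistribution, t) -> float:
    """S(t) for a distribution; t in months, t >= 0."""
    return dist.sf(t)


def median(dist: ParametricDistribution) -> float:
    """The time at which S crosses 1/2 (closed form per family)."""
    m = dist.median()
    if math.isfinite(m):
        # guard against closed-form slips for oddly scaled inputs
        if abs(dist.sf(m) - 0.5) > 1e-9:
            m = optimize.brentq(lambda t: dist.sf(t) - 0.5, 1e-12, 1e9)
    return m


def mean_survival(dist: ParametricDistribution, horizon: float) -> float:
    """Restricted mean survival time: integral of S over [0, horizon] months."""
    if not (horizon > 0):
        raise ValueError("horizon must be > 0")
    value, _ = integrate.quad(dist.sf, 0.0, horizon, limit=200)
    return value
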