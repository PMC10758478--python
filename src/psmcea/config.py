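"""Model configuration: loading, validation, and dotted-path access.

All model inputs — survival parameters, unit costs, dosing, adverse-event
profiles, utilities, sensitivity ranges — live in a single nested mapping,
bundled as ``data/default_config.yaml`` and editable as YAML.  Nothing is
hard-coded in the analysis logic.
"""

from __future__ import annotations

import copy
import hashlib
from importlib import resources
from typing import Any

import yaml

from .survival import FAMILIES, PARAM_NAMES, ParametricDistribution

__all__ = [
    "ConfigError",
    "load_config",
    "default_config",
    "default_config_text",
    "validate_config",
    "get_param",
    "set_param",
    "distribution_from_config",
]


class ConfigError(ValueError):
    """A configuration problem, reported with the offending field path."""


def _fail(path: str, msg: str) -> None:
    raise ConfigError(f"{path}: {msg}")


def default_config_text() -> str:
    """Raw text of the bundled default configuration."""
    return (
        resources.files("psmcea").joinpath("data/default_config.yaml").read_text()
    )


def default_config_checksum() -> str:
    return hashlib.sha256(default_config_text().encode()).hexdigest()


def default_config() -> dict:
    """The bundled default configuration as a validated dict."""
    cfg = yaml.safe_load(default_config_text())
    validate_config(cfg)
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def get_param(cfg: dict, dotted: str) -> Any:
    node: Any = cfg
    for key in dotted.split("."):
        try:
            node = node[key]
        except (KeyError, TypeError):
            _fail(dotted, "parameter id not found")
    return node


def set_param(cfg: dict, dotted: str, value: Any) -> dict:
    """Return a deep copy of cfg with the dotted path set to value."""
    out = copy.deepcopy(cfg)
    keys = dotted.split(".")
    node = out
    for key in keys[:-1]:
        try:
            node = node[key]
        except (KeyError, TypeError):
            _fail(dotted, "parameter id not found")
    if not isinstance(node, dict) or keys[-1] not in node:
        _fail(dotted, "parameter id not found")
    node[keys[-1]] = value
    return out


def distribution_from_config(entry: dict, path: str = "survival") -> ParametricDistribution:
    if not isinstance(entry, dict) or "family" not in entry or "params" not in entry:
        _fail(path, "expected {family, params}")
    if entry["family"] not in FAMILIES:
        _fail(f"{path}.family", f"unknown family {entry['family']!r}")
    try:
        return ParametricDistribution(entry["family"], entry["params"])
    except ValueError as exc:
        _fail(f"{path}.params", str(exc))
    raise AssertionError  # pragma: no cover


def _require(node: dict, key: str, path: str, types=None):
    if not isinstance(node, dict) or key not in node:
        _fail(f"{path}.{key}" if path else key, "missing required field")
    value = node[key]
    if types is not None and not isinstance(value, types):
        _fail(f"{path}.{key}", f"expected {types}, got {type(value).__name__}")
    return value


def _check_nonneg(value, path):
    if not isinstance(value, (int, float)) or value < 0:
        _fail(path, f"must be a nonnegative number, got {value!r}")


def _check_prob(value, path):
    _check_nonneg(value, path)
    if value > 1:
        _fail(path, f"must lie in [0, 1], got {value!r}")


def validate_config(cfg: dict) -> None:
    """Validate structure and domains; raise ConfigError with a field path."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")

    model = _require(cfg, "model", "", dict)
    for key in ("cycle_length_months", "days_per_cycle"):
        v = _require(model, key, "model", (int, float))
        if v <= 0:
            _fail(f"model.{key}", "must be > 0")
    horizon = _require(model, "horizon_cycles", "model", int)
    if horizon < 1:
        _fail("model.horizon_cycles", "must be >= 1")
    _check_prob(_require(model, "annual_discount", "model", (int, float)),
                "model.annual_discount")
    if _require(model, "eval_point", "model", str) not in ("start", "mid", "end"):
        _fail("model.eval_point", "must be one of start, mid, end")
    if _require(model, "treatment_duration", "model", str) not in (
        "until_progression", "until_death"
    ):
        _fail("model.treatment_duration", "must be until_progression or until_death")
    bg = _require(model, "background_mortality", "model", dict)
    if "annual_prob" in bg:
        _check_prob(bg["annual_prob"], "model.background_mortality.annual_prob")

    surv = _require(cfg, "survival", "", dict)
    for pop, arms in surv.items():
        for arm, curves in arms.items():
            for which in ("pfs", "os"):
                entry = _require(curves, which, f"survival.{pop}.{arm}", dict)
                distribution_from_config(entry, f"survival.{pop}.{arm}.{which}")

    drugs = _require(cfg, "drugs", "", dict)
    for name, spec in drugs.items():
        path = f"drugs.{name}"
        _check_nonneg(_require(spec, "unit_cost", path, (int, float)), f"{path}.unit_cost")
        unit = _require(spec, "unit_size_mg", path, (int, float))
        if unit <= 0:
            _fail(f"{path}.unit_size_mg", "must be > 0")
        route = _require(spec, "route", path, str)
        if route == "oral":
            _check_nonneg(_require(spec, "mg_per_day", path, (int, float)),
                          f"{path}.mg_per_day")
        elif route == "intramuscular":
            for key in ("mg_per_injection", "injections_cycle1", "injections_per_cycle"):
                _check_nonneg(_require(spec, key, path, (int, float)), f"{path}.{key}")
        else:
            _fail(f"{path}.route", "must be oral or intramuscular")

    costs = _require(cfg, "costs", "", dict)
    for key in ("follow_up", "after_progression", "subsequent_treatment",
                "end_of_life", "administration"):
        _check_nonneg(_require(costs, key, "costs", (int, float)), f"costs.{key}")

    ae = _require(cfg, "adverse_events", "", dict)
    for name, v in _require(ae, "cost_per_event", "adverse_events", dict).items():
        _check_nonneg(v, f"adverse_events.cost_per_event.{name}")
    for name, v in _require(ae, "disutility_per_year", "adverse_events", dict).items():
        _check_nonneg(v, f"adverse_events.disutility_per_year.{name}")
    risks = _require(ae, "risks", "adverse_events", dict)
    for profile, events in risks.items():
        for name, v in events.items():
            _check_prob(v, f"adverse_events.risks.{profile}.{name}")
            if name not in ae["cost_per_event"]:
                _fail(f"adverse_events.risks.{profile}.{name}", "no cost for this event")

    utilities = _require(cfg, "utilities", "", dict)
    for state in ("PF", "PD"):
        _check_prob(_require(utilities, state, "utilities", (int, float)),
                    f"utilities.{state}")

    strategies = _require(cfg, "strategies", "", dict)
    for name, spec in strategies.items():
        path = f"strategies.{name}"
        comps = _require(spec, "components", path, list)
        if not comps:
            _fail(f"{path}.components", "must be nonempty")
        total = 0.0
        for i, comp in enumerate(comps):
            drug = _require(comp, "drug", f"{path}.components[{i}]", str)
            if drug not in drugs:
                _fail(f"{path}.components[{i}].drug", f"unknown drug {drug!r}")
            w = _require(comp, "weight", f"{path}.components[{i}]", (int, float))
            _check_prob(w, f"{path}.components[{i}].weight")
            total += w
        if abs(total - 1.0) > 1e-9:
            _fail(f"{path}.components", f"weights must sum to 1, got {total}")
        profile = _require(spec, "ae_profile", path, str)
        if profile not in risks:
            _fail(f"{path}.ae_profile", f"unknown adverse-event profile {profile!r}")

    comparisons = _require(cfg, "comparisons", "", dict)
    for pop, pair in comparisons.items():
        if pop not in surv:
            _fail(f"comparisons.{pop}", "no survival curves for this population")
        if not isinstance(pair, list) or len(pair) != 2:
            _fail(f"comparisons.{pop}", "expected [intervention, comparator]")
        for strat in pair:
            if strat not in strategies:
                _fail(f"comparisons.{pop}", f"unknown strategy {strat!r}")
            if strat not in surv[pop]:
                _fail(f"comparisons.{pop}", f"no curves for strategy {strat!r}")

    _check_nonneg(_require(cfg, "wtp", "", (int, float)), "wtp")

    for i, entry in enumerate(cfg.get("dsa", [])):
        path = f"dsa[{i}]"
        dotted = _require(entry, "param", path, str)
        base = get_param(cfg, dotted)
        if not isinstance(base, (int, float)):
            _fail(f"{path}.param", f"{dotted} is not a numeric parameter")
        lo = _require(entry, "low", path, (int, float))
        hi = _require(entry, "high", path, (int, float))
        lo, hi = min(lo, hi), max(hi, lo)
        if not (lo <= base <= hi):
            _fail(path, f"base value {base} outside sorted range [{lo}, {hi}]")

    psa = cfg.get("psa", {})
    if psa:
        n = _require(psa, "n_iterations", "psa", int)
        if n < 1:
            _fail("psa.n_iterations", "must be >= 1")
        if _require(psa, "utility_distribution", "psa", str) not in ("beta", "normal"):
            _fail("psa.utility_distribution", "must be beta or normal")
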