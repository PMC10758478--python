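"""The partitioned survival engine: occupancy, accumulation, incrementals."""

import math

import numpy as np
import pytest

from psmcea.economics import (AdverseEventProfile, DrugRegimen, EconomicInputs,
                              StrategySpec)
from psmcea.engine import (PSMConfig, accumulate, compute_occupancy,
                           incremental, run_cea)
from psmcea.survival import ParametricDistribution

ELA_OS = ParametricDistribution("lognormal", {"meanlog": 3.192779, "sdlog": 0.851157})
ELA_PFS = ParametricDistribution("lognormal", {"meanlog": 1.414933, "sdlog": 0.958343})

NO_AE = AdverseEventProfile(())
ORAL = DrugRegimen("oral_drug", unit_cost=1.0, unit_size_mg=1.0, route="oral",
                   mg_per_day=100.0)
STRATEGY = StrategySpec("S", ((ORAL, 1.0),), NO_AE)
ECON = EconomicInputs(u_pf=0.837, u_pd=0.443, follow_up=2959.0,
                      after_progression=6549.0, subsequent_treatment=9061.0,
                      end_of_life=2601.0, administration=702.0)


class TestOccupancy:
    def test_everyone_starts_progression_free(self):
        cfg = PSMConfig(eval_point="start")
        trace = compute_occupancy(ELA_PFS, ELA_OS, cfg)
        first = trace.table.iloc[0]
        assert (first["pf"], first["pd"], first["dead"]) == (1.0, 0.0, 0.0)

    def test_identical_curves_leave_progressed_state_empty(self):
        trace = compute_occupancy(ELA_OS, ELA_OS, PSMConfig())
        assert np.all(trace.table["pd"].to_numpy() == 0.0)

    def test_dead_fraction_at_horizon_matches_survival_oracle(self):
        # frozen from the direct lognormal CDF at t = 120 months
        trace = compute_occupancy(ELA_PFS, ELA_OS, PSMConfig(eval_point="end"))
        assert trace.table["dead"].iloc[-1] == pytest.approx(0.9695059945, abs=1e-9)

    def test_pfs_above_os_is_clipped_not_an_error(self):
        slow_pfs = ParametricDistribution("lognormal", {"meanlog": 5.0, "sdlog": 0.5})
        trace = compute_occupancy(slow_pfs, ELA_OS, PSMConfig())
        assert trace.clipped_cycles > 0
        assert np.all(trace.table["pd"].to_numpy() >= 0.0)

    def test_background_mortality_floor_caps_survival(self):
        cfg = PSMConfig(background_annual_prob=0.5, eval_point="end")
        trace = compute_occupancy(ELA_PFS, ELA_OS, cfg)
        alive = 1.0 - trace.table["dead"].to_numpy()
        floor = 0.5 ** (trace.table["t_eval"].to_numpy() / 12.0)
        assert np.all(alive <= floor + 1e-12)

    def test_conservation_and_monotonicity_over_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pfs = ParametricDistribution(
                "weibull", {"shape": rng.uniform(0.5, 3), "scale": rng.uniform(1, 20)})
            os_ = ParametricDistribution(
                "lognormal", {"meanlog": rng.uniform(1, 4), "sdlog": rng.uniform(0.3, 1.5)})
            cfg = PSMConfig(eval_point=rng.choice(["start", "mid", "end"]))
            tab = compute_occupancy(pfs, os_, cfg).table
            total = tab["pf"] + tab["pd"] + tab["dead"]
            np.testing.assert_allclose(total, 1.0, atol=1e-12)
            assert np.all(np.diff(tab["dead"]) >= -1e-12)
            assert np.all(tab[["pf", "pd", "dead"]].to_numpy() >= -1e-15)


class TestAccumulation:
    def test_unit_utilities_without_discounting_make_qalys_equal_lys(self):
        cfg = PSMConfig(annual_discount=0.0)
        econ = EconomicInputs(1.0, 1.0, 0, 0, 0, 0, 0)
        trace = compute_occupancy(ELA_PFS, ELA_OS, cfg)
        out = accumulate(trace, STRATEGY, econ, cfg)
        assert out.total_qalys == pytest.approx(out.total_lys, rel=1e-12)

    def test_discount_factor_definition(self):
        cfg = PSMConfig(annual_discount=0.03)
        assert cfg.discount_factor(12.0) == pytest.approx(1 / 1.03, rel=1e-12)

    def test_end_of_life_cost_bounded_and_matches_brute_force(self):
        cfg = PSMConfig(eval_point="start")
        econ = EconomicInputs(0.837, 0.443, 0, 0, 0, 2601.0, 0)
        trace = compute_occupancy(ELA_PFS, ELA_OS, cfg)
        free = StrategySpec("free", ((DrugRegimen("x", 0.0, 1.0, "oral", 0.0), 1.0),),
                            NO_AE)
        out = accumulate(trace, free, econ, cfg)
        # telescoping bound: total incident deaths <= 1
        assert out.total_cost <= 2601.0 + 1e-9
        df = cfg.discount_factor(trace.table["t_eval"].to_numpy())
        brute = float(np.sum(trace.table["incident_death"].to_numpy() * 2601.0 * df))
        assert out.total_cost == pytest.approx(brute, rel=1e-12)

    def test_discounting_only_shrinks_totals(self):
        undisc = PSMConfig(annual_discount=0.0)
        disc = PSMConfig(annual_discount=0.03)
        for cfg0, cfg1 in ((undisc, disc),):
            o0 = accumulate(compute_occupancy(ELA_PFS, ELA_OS, cfg0), STRATEGY, ECON, cfg0)
            o1 = accumulate(compute_occupancy(ELA_PFS, ELA_OS, cfg1), STRATEGY, ECON, cfg1)
            assert o1.total_cost < o0.total_cost
            assert o1.total_qalys < o0.total_qalys
            assert o1.total_lys < o0.total_lys

    def test_monotone_in_utilities_and_unit_costs(self, cfg):
        import copy

        from psmcea.engine import run_cea as run

        base = run(cfg, "overall")
        up = copy.deepcopy(cfg)
        up["utilities"]["PF"] = 0.9
        more_q = run(up, "overall")
        assert more_q.outcomes["ELA"].total_qalys > base.outcomes["ELA"].total_qalys
        pricier = copy.deepcopy(cfg)
        pricier["costs"]["follow_up"] = 4000
        assert (run(pricier, "overall").outcomes["ELA"].total_cost
                > base.outcomes["ELA"].total_cost)

    def test_daily_subcycles_stay_within_half_cycle_bound(self):
        monthly = PSMConfig(cycle_length=1.0, horizon_cycles=120, eval_point="start")
        daily = PSMConfig(cycle_length=1.0 / 30, horizon_cycles=3600, eval_point="start")
        om = accumulate(compute_occupancy(ELA_PFS, ELA_OS, monthly), STRATEGY, ECON,
                        monthly)
        od = accumulate(compute_occupancy(ELA_PFS, ELA_OS, daily), STRATEGY, ECON,
                        daily)
        # half-cycle bound: horizon x (max per-cycle increment difference)
        max_step = float(om.trace.table["qaly"].abs().max())
        assert abs(om.total_qalys - od.total_qalys) <= 120 * max_step
        # and in practice the agreement is much tighter than the bound
        assert od.total_qalys == pytest.approx(om.total_qalys, rel=0.05)


class TestIncrementals:
    def _outcome(self, cost, qaly, ly=2.0, name="x"):
        from psmcea.engine import StrategyOutcome

        return StrategyOutcome(name, cost, qaly, ly)

    def test_identical_strategies_have_undefined_icer(self):
        a = self._outcome(100.0, 1.0)
        d_cost, d_qaly, _, icer, dominance = incremental(a, a)
        assert d_cost == 0.0 and d_qaly == 0.0
        assert math.isnan(icer) and dominance == "undefined"

    def test_dominance_flagged_when_signs_differ(self):
        cheap_better = self._outcome(50.0, 2.0)
        dear_worse = self._outcome(100.0, 1.0)
        *_, dominance = incremental(cheap_better, dear_worse)
        assert dominance == "intervention dominates"
        *_, dominance = incremental(dear_worse, cheap_better)
        assert dominance == "comparator dominates"

    def test_icer_is_cost_ratio(self):
        a, b = self._outcome(900.0, 3.0), self._outcome(400.0, 2.0)
        d_cost, d_qaly, _, icer, dominance = incremental(a, b)
        assert icer == pytest.approx(500.0)
        assert dominance == ""


class TestRunCEA:
    def test_base_case_structure(self, cfg):
        result = run_cea(cfg, "overall")
        assert set(result.outcomes) == {"ELA", "SOC", "FUL"}
        assert result.intervention == "ELA" and result.comparator == "SOC"
        assert result.incr_cost == pytest.approx(
            result.outcomes["ELA"].total_cost - result.outcomes["SOC"].total_cost)
        assert result.icer == pytest.approx(result.incr_cost / result.incr_qalys)

    def test_esr1_pairs_against_fulvestrant(self, cfg):
        result = run_cea(cfg, "esr1")
        assert result.comparator == "FUL"
        assert result.icer > 0

    def test_unknown_population_rejected(self, cfg):
        with pytest.raises(ValueError):
            run_cea(cfg, "nonexistent")
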