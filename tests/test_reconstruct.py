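"""KM inversion into pseudo-IPD, censored MLE fitting, and model selection."""

import math

import numpy as np
import pytest
from lifelines import KaplanMeierFitter, LogNormalFitter

from psmcea.reconstruct import (DigitizedCurve, FitError, ReconstructedIPD,
                                RiskTable, SurvivalFitResult, fit_all_families,
                                fit_distribution, fit_table,
                                read_digitized_curve, read_risk_table,
                                reconstruct_ipd, select_best)
from psmcea.survival import ParametricDistribution
from psmcea.synthdata import (SyntheticCurveSpec, simulate_km, write_curve_csv,
                              write_risk_csv)


def km_at(ipd, times):
    kmf = KaplanMeierFitter().fit(ipd.times, ipd.events)
    return kmf.survival_function_at_times(times).to_numpy()


class TestTypes:
    def test_curve_normalized_to_start_at_one(self):
        c = DigitizedCurve(((1.0, 0.8), (2.0, 0.5)))
        assert c.points[0] == (0.0, 1.0)

    @pytest.mark.parametrize("points", [
        (),
        ((0.0, 1.0), (1.0, 1.1)),
        ((0.0, 1.0), (1.0, 0.5), (1.0, 0.4)),
        ((0.0, 1.0), (1.0, 0.5), (2.0, 0.6)),
    ])
    def test_invalid_curves_rejected(self, points):
        with pytest.raises(ValueError):
            DigitizedCurve(points)

    def test_risk_table_must_be_nonincreasing(self):
        with pytest.raises(ValueError):
            RiskTable(((0.0, 100), (6.0, 120)))


class TestReconstruction:
    def test_no_censoring_inversion_is_exact(self):
        curve = DigitizedCurve(((0, 1.0), (1, 2 / 3), (2, 1 / 3), (3, 0.0)))
        ipd = reconstruct_ipd(curve, RiskTable(((0, 3),)))
        assert sorted(ipd.records) == [(1.0, 1), (2.0, 1), (3.0, 1)]

    def test_flat_segment_with_attrition_yields_censoring(self):
        # survival flat on [2, 6) while at-risk drops: censoring, not events
        curve = DigitizedCurve(((0, 1.0), (1, 0.9), (2, 0.8), (6, 0.8), (8, 0.5)))
        risk = RiskTable(((0, 100), (2, 80), (6, 60)))
        ipd = reconstruct_ipd(curve, risk)
        assert len(ipd) == 100
        in_flat = [(t, e) for t, e in ipd.records if 2.0 < t < 6.0]
        assert in_flat and all(e == 0 for _, e in in_flat)

    def test_roundtrip_recovers_km_within_tolerance(self):
        spec = SyntheticCurveSpec(
            ParametricDistribution("weibull", {"shape": 1.3, "scale": 10.0}),
            n_subjects=200, censoring_mechanism="uniform", censoring_rate=0.2,
            grid_step=1.0, seed=7)
        curve, risk, _truth = simulate_km(spec)
        ipd = reconstruct_ipd(curve, risk)
        assert len(ipd) == risk.n_initial
        delta = np.abs(km_at(ipd, curve.times) - curve.survival)
        assert float(delta.max()) <= 0.02

    def test_roundtrip_error_shrinks_with_digitization_density(self):
        truth_dist = ParametricDistribution("lognormal", {"meanlog": 2.0, "sdlog": 0.8})
        errs = []
        for step in (4.0, 0.5):
            spec = SyntheticCurveSpec(truth_dist, 300, "uniform", 0.15,
                                      grid_step=step, seed=11)
            curve, risk, _ = simulate_km(spec)
            ipd = reconstruct_ipd(curve, risk)
            errs.append(float(np.abs(km_at(ipd, curve.times) - curve.survival).max()))
        assert errs[1] <= errs[0]

    def test_conservation_under_heavy_censoring(self):
        spec = SyntheticCurveSpec(
            ParametricDistribution("gamma", {"shape": 2.0, "scale": 6.0}),
            n_subjects=150, censoring_mechanism="uniform", censoring_rate=0.4,
            grid_step=2.0, seed=3)
        curve, risk, _ = simulate_km(spec)
        ipd = reconstruct_ipd(curve, risk)
        assert int(ipd.events.sum()) + int((1 - ipd.events).sum()) == risk.n_initial

    def test_bad_inputs_rejected(self):
        curve = DigitizedCurve(((0, 1.0), (1, 0.5), (2, 0.2)))
        with pytest.raises(ValueError):
            reconstruct_ipd(curve, RiskTable(((0, 1),)))  # n < 2
        with pytest.raises(ValueError):
            reconstruct_ipd(curve, RiskTable(((0, 50), (1, 0))))  # zero before end


class TestFitting:
    def test_information_criteria_formulas(self):
        d = ParametricDistribution("weibull", {"shape": 1.0, "scale": 1.0})
        fit = SurvivalFitResult(dist=d, loglik=-100.0, aic=204.0,
                                bic=2 * math.log(50) - 2 * -100.0, n=50)
        assert fit.aic == 2 * 2 - 2 * fit.loglik == 204.0
        assert fit.bic == pytest.approx(2 * math.log(50) + 200.0)

    def test_parameter_recovery_lognormal_n5000(self):
        spec = SyntheticCurveSpec(
            ParametricDistribution("lognormal", {"meanlog": 1.63382, "sdlog": 1.03730}),
            n_subjects=5000, censoring_rate=0.0, seed=1)
        _, _, truth = simulate_km(spec)
        fit = fit_distribution(truth, "lognormal")
        assert fit.dist.params["meanlog"] == pytest.approx(1.63382, abs=0.05)
        assert fit.dist.params["sdlog"] == pytest.approx(1.03730, abs=0.05)

    def test_true_family_beats_misspecified_across_seeds(self):
        """AIC prefers the generating family in >= 18 of 20 replicates."""
        truth_dist = ParametricDistribution(
            "lognormal", {"meanlog": 1.63382, "sdlog": 1.03730})
        wins = 0
        for seed in range(20):
            spec = SyntheticCurveSpec(truth_dist, 5000, seed=seed)
            _, _, truth = simulate_km(spec)
            ln = fit_distribution(truth, "lognormal")
            wb = fit_distribution(truth, "weibull")
            wins += ln.aic < wb.aic
        assert wins >= 18

    def test_censored_likelihood_matches_lifelines(self):
        spec = SyntheticCurveSpec(
            ParametricDistribution("lognormal", {"meanlog": 2.2, "sdlog": 0.7}),
            n_subjects=500, censoring_mechanism="uniform", censoring_rate=0.2, seed=5)
        _, _, truth = simulate_km(spec)
        ours = fit_distribution(truth, "lognormal")
        lnf = LogNormalFitter().fit(truth.times, truth.events)
        assert ours.dist.params["meanlog"] == pytest.approx(lnf.mu_, abs=1e-3)
        assert ours.dist.params["sdlog"] == pytest.approx(lnf.sigma_, abs=1e-3)

    def test_too_few_events_raise(self):
        with pytest.raises(FitError):
            fit_distribution(ReconstructedIPD(((1.0, 1), (2.0, 0), (3.0, 0))),
                             "weibull")
        with pytest.raises(FitError):
            fit_distribution(ReconstructedIPD(tuple((float(t), 0) for t in range(1, 30))),
                             "lognormal")


class TestSelection:
    def _fit(self, family, aic, bic):
        d = ParametricDistribution("weibull", {"shape": 1.0, "scale": 1.0})
        if family != "weibull":
            d = ParametricDistribution("lognormal", {"meanlog": 0.0, "sdlog": 1.0})
        return SurvivalFitResult(dist=d, loglik=0.0, aic=aic, bic=bic, n=10)

    def test_single_fit_returns_itself(self):
        fit = self._fit("weibull", 100.0, 101.0)
        assert select_best([fit]) is fit

    def test_minimum_aic_then_bic_then_family_order(self):
        a = self._fit("lognormal", 100.0, 105.0)
        b = self._fit("weibull", 101.0, 100.0)
        assert select_best([a, b]) is a
        c = self._fit("weibull", 100.0, 104.0)
        assert select_best([a, c]) is c  # AIC tie -> lower BIC
        d = self._fit("weibull", 100.0, 105.0)
        assert select_best([a, d]) is d  # full tie -> canonical family order

    def test_recovery_experiment_selects_generating_family(self):
        spec = SyntheticCurveSpec(
            ParametricDistribution("lognormal", {"meanlog": 1.63382, "sdlog": 1.03730}),
            n_subjects=5000, seed=1)
        _, _, truth = simulate_km(spec)
        fits = fit_all_families(truth)
        assert select_best(fits).family == "lognormal"
        table = fit_table(fits)
        assert list(table["family"]) and table["aic"].is_monotonic_increasing

    def test_information_criterion_differences_invariant_to_shift(self):
        # a constant added to every log-likelihood cancels in AIC/BIC deltas
        fits = [self._fit("lognormal", 2 * 2 - 2 * ll, 2 * math.log(10) - 2 * ll)
                for ll in (-50.0, -60.0)]
        shifted = [self._fit("lognormal", 2 * 2 - 2 * (ll + 7.0),
                             2 * math.log(10) - 2 * (ll + 7.0))
                   for ll in (-50.0, -60.0)]
        assert (fits[1].aic - fits[0].aic) == pytest.approx(
            shifted[1].aic - shifted[0].aic)
        assert (fits[1].bic - fits[0].bic) == pytest.approx(
            shifted[1].bic - shifted[0].bic)


def test_csv_roundtrip(tmp_path):
    spec = SyntheticCurveSpec(
        ParametricDistribution("weibull", {"shape": 1.2, "scale": 8.0}),
        n_subjects=50, seed=2)
    curve, risk, _ = simulate_km(spec)
    write_curve_csv(curve, tmp_path / "c.csv")
    write_risk_csv(risk, tmp_path / "r.csv")
    back = read_digitized_curve(tmp_path / "c.csv")
    np.testing.assert_allclose(back.times, curve.times, rtol=0, atol=0)
    np.testing.assert_allclose(back.survival, curve.survival, rtol=1e-12)
    assert read_risk_table(tmp_path / "r.csv").intervals == risk.intervals
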