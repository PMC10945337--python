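import math

import numpy as np
import pytest
from scipy.integrate import quad

from hybridose.kinetics import (
    FitResult,
    TimeActivityCurve,
    effective_half_life,
    fit_monoexp,
    rescale_tac,
    tiac,
)
from hybridose.nuclides import decay_constant, load_nuclide
from hybridose.warn import DataQualityWarning


def _tac(times, a0, lam, region="r"):
    return TimeActivityCurve(region, tuple(times),
                             tuple(a0 * math.exp(-lam * t) for t in times))


class TestFitMonoexp:
    @pytest.mark.parametrize("weighting", ["uniform", "inverse_activity"])
    def test_exact_samples_recovered(self, weighting):
        fit = fit_monoexp(_tac([24, 48, 96], 10.0, 0.05), weighting=weighting)
        assert fit.A0_percentIA == pytest.approx(10.0, rel=1e-9)
        assert fit.lambda_eff_per_h == pytest.approx(0.05, rel=1e-9)

    def test_two_point_closed_form(self):
        # through (0, 8) and (10, 4): lambda = ln2/10, A0 = 8
        fit = fit_monoexp(TimeActivityCurve("r", (0.0, 10.0), (8.0, 4.0)),
                          weighting="uniform")
        assert fit.A0_percentIA == pytest.approx(8.0, rel=1e-12)
        assert fit.lambda_eff_per_h == pytest.approx(math.log(2) / 10, rel=1e-12)

    def test_sigma_weighting_requires_sigma(self):
        with pytest.raises(ValueError):
            fit_monoexp(_tac([1, 2, 3], 5, 0.1), weighting="sigma")

    def test_non_decaying_flagged_not_fatal(self):
        tac = TimeActivityCurve("r", (0.0, 10.0, 20.0), (1.0, 2.0, 3.0))
        with pytest.warns(DataQualityWarning, match="NON_DECAYING"):
            fit = fit_monoexp(tac)
        assert "NON_DECAYING" in fit.warnings
        assert fit.A0_percentIA > 0

    def test_lambda_below_physical_warns(self):
        tb = load_nuclide("Tb161")
        slow = decay_constant(tb) / 2  # slower than physical decay alone
        with pytest.warns(DataQualityWarning, match="LAMBDA_BELOW_PHYSICAL"):
            fit = fit_monoexp(_tac([24, 48, 96], 5.0, slow), nuclide=tb)
        assert "LAMBDA_BELOW_PHYSICAL" in fit.warnings

    def test_fewer_than_two_positive_samples_raises(self):
        tac = TimeActivityCurve("r", (1.0, 2.0, 3.0), (0.0, 0.0, 4.0))
        with pytest.raises(ValueError):
            fit_monoexp(tac)

    def test_weighting_recorded(self):
        fit = fit_monoexp(_tac([1, 2, 3], 5, 0.1))
        assert fit.weights_used == "inverse_activity"

    def test_noisy_median_recovery_within_tolerance(self):
        rng = np.random.default_rng(42)
        a0s, lams = [], []
        for _ in range(100):
            t = np.array([24.0, 48.0, 96.0])
            a = 10.0 * np.exp(-0.03 * t) * (1 + rng.normal(0, 0.02, 3))
            fit = fit_monoexp(TimeActivityCurve("r", tuple(t), tuple(a)))
            a0s.append(fit.A0_percentIA)
            lams.append(fit.lambda_eff_per_h)
        assert np.median(a0s) == pytest.approx(10.0, rel=0.05)
        assert np.median(lams) == pytest.approx(0.03, rel=0.05)


class TestEffectiveHalfLife:
    def test_ln2_over_lambda(self):
        fit = FitResult("r", 1.0, math.log(2) / 10, "uniform", 0.0)
        assert effective_half_life(fit) == pytest.approx(10.0)

    def test_pure_physical_decay_gives_physical_half_life(self):
        tb = load_nuclide("Tb161")
        fit = FitResult("r", 1.0, decay_constant(tb), "uniform", 0.0)
        assert effective_half_life(fit) == pytest.approx(165.744)

    def test_table_scale_kidney_rate(self):
        fit = FitResult("r", 1.0, 0.021, "uniform", 0.0)
        assert effective_half_life(fit) == pytest.approx(33.0, abs=0.1)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            effective_half_life(FitResult("r", 1.0, 0.0, "uniform", 0.0))


class TestTiac:
    def test_a0_over_100_lambda(self):
        fit = FitResult("r", 10.0, 0.1, "uniform", 0.0)
        assert tiac(fit).tiac_h == pytest.approx(1.0)

    def test_pure_physical_decay_limit(self):
        lu = load_nuclide("Lu177")
        fit = FitResult("r", 100.0, decay_constant(lu), "uniform", 0.0)
        assert tiac(fit).tiac_h == pytest.approx(230.1, abs=0.1)

    def test_halving_lambda_doubles_tiac(self):
        t1 = tiac(FitResult("r", 10.0, 0.1, "uniform", 0.0)).tiac_h
        t2 = tiac(FitResult("r", 10.0, 0.05, "uniform", 0.0)).tiac_h
        assert t2 == pytest.approx(2 * t1)

    def test_t_start_shifts_by_decay_factor(self):
        fit = FitResult("r", 10.0, 0.1, "uniform", 0.0)
        assert tiac(fit, t_start=24.0).tiac_h == pytest.approx(
            tiac(fit).tiac_h * math.exp(-0.1 * 24))

    @pytest.mark.parametrize("a0, lam", [(10.0, 0.1), (2.64, 0.021), (0.4, 0.004)])
    def test_analytic_equals_quadrature(self, a0, lam):
        fit = FitResult("r", a0, lam, "uniform", 0.0)
        t_half = math.log(2) / lam
        head, _ = quad(lambda t: (a0 / 100) * math.exp(-lam * t),
                       0, 20 * t_half, limit=200)
        tail = (a0 / 100) * math.exp(-lam * 20 * t_half) / lam
        assert tiac(fit).tiac_h == pytest.approx(head + tail, rel=1e-8)


class TestRescaleTac:
    def test_ratio_rule(self):
        tac = _tac([24, 48, 96], 10.0, 0.05)
        fit = fit_monoexp(tac)
        predicted = fit.predict(48.0)
        scaled = rescale_tac(tac, (48.0, 1.5 * predicted))
        assert scaled.provenance == "rescaled"
        for orig, new in zip(tac.percent_ia, scaled.percent_ia):
            assert new == pytest.approx(1.5 * orig, rel=1e-9)

    def test_identity_when_spect_matches_prediction(self):
        tac = _tac([24, 48, 96], 10.0, 0.05)
        predicted = fit_monoexp(tac).predict(48.0)
        scaled = rescale_tac(tac, (48.0, predicted))
        assert scaled.percent_ia == pytest.approx(tac.percent_ia, rel=1e-12)

    def test_scale_equivariance_of_downstream_fit(self):
        tac = _tac([24, 48, 96], 10.0, 0.05)
        fit0 = fit_monoexp(tac)
        scaled = rescale_tac(tac, (48.0, 2.0 * fit0.predict(48.0)))
        fit1 = fit_monoexp(scaled)
        assert fit1.A0_percentIA == pytest.approx(2 * fit0.A0_percentIA, rel=1e-9)
        assert fit1.lambda_eff_per_h == pytest.approx(
            fit0.lambda_eff_per_h, rel=1e-9)

    def test_spect_time_outside_window_rejected(self):
        tac = _tac([24, 48, 96], 10.0, 0.05)
        with pytest.raises(ValueError, match="SPECT time"):
            rescale_tac(tac, (130.0, 1.0))

    def test_planar_calibration_bias_removed_by_exact_spect(self, noiseless_spec):
        """Hybrid rescaling: a miscalibrated planar curve rescaled by an
        exact SPECT point reproduces the true kinetics."""
        spec = noiseless_spec
        region = spec.regions[0]
        times = spec.acquisition_times_h
        bias = 0.65  # planar chain off by a constant factor
        tac = TimeActivityCurve(
            region.region_id, times,
            tuple(bias * spec.true_percent_ia(region.region_id, t)
                  for t in times))
        truth_at_spect = spec.true_percent_ia(region.region_id, spec.spect_time_h)
        rescaled = rescale_tac(tac, (spec.spect_time_h, truth_at_spect))
        for t, a in zip(rescaled.times_h, rescaled.percent_ia):
            assert a == pytest.approx(
                spec.true_percent_ia(region.region_id, t), rel=1e-9)
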