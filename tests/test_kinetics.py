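"""Kinetic inference: initial rates, reaction orders, apparent Km,
substrate inhibition, and the estimator API."""

import numpy as np
import pytest
from sklearn.base import clone

from autometh import (
    ConvergenceError,
    InputError,
    KineticSimConfig,
    LinearRateFit,
    MichaelisMentenFit,
    ReactionOrderFit,
    SubstrateInhibitionFit,
    TimeCourse,
    fit_mm,
    fit_rate,
    fit_reaction_order,
    fit_substrate_inhibition,
    simulate_mm_data,
    simulate_order_data,
    simulate_timecourse,
)
from autometh.kinetics import michaelis_menten, substrate_inhibition


class TestRateFit:
    def test_exact_line_recovered(self):
        t = np.linspace(0, 4, 6)
        est = fit_rate(TimeCourse(t=t, signal=704.0 * t))
        assert est.slope == pytest.approx(704.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_constant_signal_zero_slope(self):
        t = np.array([0.0, 1.0, 2.0])
        est = fit_rate(TimeCourse(t=t, signal=np.full(3, 5.0)))
        assert est.slope == pytest.approx(0.0)

    def test_noisy_slope_recovery_median(self):
        """Simulated slope-212 time courses (5% CV, 6 points): the median
        recovered slope over many seeds stays within 10% of truth."""
        slopes = [
            fit_rate(simulate_timecourse(212.0, KineticSimConfig(noise_cv=0.05, seed=s))).slope
            for s in range(500)
        ]
        assert abs(np.median(slopes) - 212.0) / 212.0 < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError, match=">= 3"):
            fit_rate(TimeCourse(t=[0.0, 1.0], signal=[0.0, 1.0]))

    def test_automethylation_to_histone_rate_ratio(self):
        """Time courses built from the two reference slopes reproduce the
        roughly one-third automethylation-to-H3-methylation rate ratio."""
        h3 = fit_rate(simulate_timecourse(704.0, KineticSimConfig(seed=0)))
        auto = fit_rate(simulate_timecourse(212.0, KineticSimConfig(seed=0)))
        assert auto.slope / h3.slope == pytest.approx(212 / 704, abs=1e-9)
        assert auto.slope / h3.slope == pytest.approx(0.30, abs=0.01)


class TestReactionOrder:
    @pytest.mark.parametrize("n_true", [0.5, 0.7, 1.0, 2.0])
    def test_noiseless_power_law_recovered_exactly(self, n_true):
        conc = np.array([1.0, 3.0, 10.0, 30.0])
        rate = 2.5 * conc**n_true
        fit = fit_reaction_order(conc, rate)
        assert fit.n == pytest.approx(n_true, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_first_order_band(self):
        conc = np.array([1.0, 3.0, 10.0, 30.0])
        assert fit_reaction_order(conc, 2.0 * conc**0.99).first_order()
        assert fit_reaction_order(conc, 2.0 * conc**0.7).first_order()
        assert not fit_reaction_order(conc, 2.0 * conc**2.0).first_order()

    def test_estimator_unbiased_across_seeds(self):
        """With multiplicative noise the log-log slope estimator is unbiased:
        |mean bias| < 2 SE over 500 replicates."""
        fits = [
            fit_reaction_order(
                *simulate_order_data(2.0, 0.7, KineticSimConfig(noise_cv=0.1, seed=s))
                .to_numpy().T
            )
            for s in range(500)
        ]
        ns = np.array([f.n for f in fits])
        se_mean = ns.std(ddof=1) / np.sqrt(len(ns))
        assert abs(ns.mean() - 0.7) < 2 * se_mean

    def test_non_positive_pair_named(self):
        with pytest.raises(InputError, match="pair 1"):
            fit_reaction_order([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])


class TestMichaelisMenten:
    S = np.array([1.0, 2.5, 5.0, 10.0, 20.0, 50.0, 100.0])

    def test_noiseless_recovery_to_three_decimals(self):
        v = michaelis_menten(self.S, 100.0, 10.4)
        fit = fit_mm(self.S, v)
        assert fit.km == pytest.approx(10.4, abs=1e-3)
        assert fit.vmax == pytest.approx(100.0, abs=1e-3)

    def test_scale_equivariance(self):
        v = michaelis_menten(self.S, 100.0, 6.5) * (
            1 + 0.05 * np.sin(np.arange(len(self.S)))
        )
        f1, f2 = fit_mm(self.S, v), fit_mm(self.S, 3.0 * v)
        assert f2.vmax == pytest.approx(3.0 * f1.vmax, rel=1e-6)
        assert f2.km == pytest.approx(f1.km, rel=1e-6)

    def test_saturated_data_flagged_ill_conditioned(self):
        s = np.array([50.0, 60.0, 70.0, 80.0, 90.0])
        with pytest.warns(UserWarning, match="span"):
            fit = fit_mm(s, np.full(5, 42.0))
        assert fit.ill_conditioned

    def test_noisy_km_recovery_median(self):
        kms = [
            fit_mm(*simulate_mm_data(100.0, 6.5, KineticSimConfig(noise_cv=0.1, seed=s))
                   .to_numpy().T).km
            for s in range(200)
        ]
        assert abs(np.median(kms) - 6.5) / 6.5 < 0.10

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InputError, match=">= 4"):
            fit_mm([1.0, 5.0, 20.0], [1.0, 3.0, 5.0])


class TestSubstrateInhibition:
    S = np.array([1.0, 2.5, 5.0, 10.0, 20.0, 50.0])

    def test_inhibited_data_prefers_inhibition_model(self):
        v = substrate_inhibition(self.S, 100.0, 6.5, 100.0)
        rng = np.random.default_rng(0)
        v = v * (1 + 0.02 * rng.standard_normal(len(v)))
        si, mm, preferred = fit_substrate_inhibition(self.S, v)
        assert preferred == "MM_substrate_inhibition"
        assert si.aic < mm.aic

    def test_plain_mm_data_keeps_plain_mm(self):
        v = michaelis_menten(self.S, 100.0, 6.5)
        rng = np.random.default_rng(1)
        v = v * (1 + 0.05 * rng.standard_normal(len(v)))
        _, _, preferred = fit_substrate_inhibition(self.S, v)
        assert preferred == "MM"

    def test_infinite_ki_reduces_to_plain_mm(self):
        v_inf = substrate_inhibition(self.S, 100.0, 6.5, 1e12)
        si_fit = fit_mm(self.S, v_inf)
        plain = fit_mm(self.S, michaelis_menten(self.S, 100.0, 6.5))
        assert si_fit.km == pytest.approx(plain.km, rel=1e-2)
        assert si_fit.vmax == pytest.approx(plain.vmax, rel=1e-2)


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        est = MichaelisMentenFit(min_pairs=5)
        assert est.get_params() == {"min_pairs": 5}
        assert clone(est).get_params() == {"min_pairs": 5}
        est.set_params(min_pairs=4)
        assert est.min_pairs == 4

    def test_fitted_attributes_and_predict(self):
        S = np.array([1.0, 2.5, 5.0, 10.0, 20.0])
        v = michaelis_menten(S, 50.0, 6.5)
        est = MichaelisMentenFit().fit(S.reshape(-1, 1), v)
        assert est.km_ == pytest.approx(6.5, abs=1e-6)
        np.testing.assert_allclose(est.predict(S.reshape(-1, 1)), v, rtol=1e-6)

    def test_linear_estimators_score(self):
        t = np.linspace(0, 4, 6).reshape(-1, 1)
        y = 3.0 * t.ravel() + 1.0
        assert LinearRateFit().fit(t, y).score(t, y) == pytest.approx(1.0)
        conc = np.array([1.0, 3.0, 10.0, 30.0]).reshape(-1, 1)
        est = ReactionOrderFit().fit(conc, 2.0 * conc.ravel() ** 0.7)
        np.testing.assert_allclose(est.predict(conc), 2.0 * conc.ravel() ** 0.7)

    def test_substrate_inhibition_reports_both_aics(self):
        S = np.array([1.0, 2.5, 5.0, 10.0, 20.0, 50.0])
        v = substrate_inhibition(S, 100.0, 6.5, 80.0)
        est = SubstrateInhibitionFit().fit(S, v)
        assert hasattr(est, "aic_mm_") and hasattr(est, "preferred_model_")
        assert est.ki_ == pytest.approx(80.0, rel=1e-3)
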