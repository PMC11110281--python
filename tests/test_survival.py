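"""Survival families, MLE fitting, model selection, hybrid curves,
discounted person-time."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from psmcea.survival import (
    FAMILIES,
    FitError,
    FittedModel,
    ParametricCurve,
    ParametricSurvival,
    StepCurve,
    build_hybrid_curve,
    discounted_state_time,
    fit_parametric,
    select_best,
    survival_probability,
)

from conftest import simulate_censored

EXAMPLES = {
    "exponential": (0.08,),
    "weibull": (1.3, 12.0),
    "gompertz": (0.05, 0.05),
    "loglogistic": (1.8, 9.0),
    "lognormal": (2.2773, 1.13),
    "gengamma": (2.0, 1.0, 0.5),
}


class TestSurvivalFunctions:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_proper_survival_function(self, family):
        dist = ParametricSurvival(family, EXAMPLES[family])
        grid = np.linspace(0.0, 240.0, 2000)
        s = dist.survival(grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))

    def test_lognormal_median(self):
        dist = ParametricSurvival("lognormal", (2.2773, 1.13))
        assert math.isclose(
            survival_probability(dist, math.exp(2.2773)), 0.5, abs_tol=1e-12
        )

    def test_lognormal_closed_form(self):
        # 1 - Phi((ln 12 - 1.199)/1.049), the normal-CDF oracle
        dist = ParametricSurvival("lognormal", (1.199, 1.049))
        expected = stats.norm.sf((math.log(12) - 1.199) / 1.049)
        assert math.isclose(survival_probability(dist, 12.0), expected, rel_tol=1e-12)
        assert math.isclose(expected, 0.1101, abs_tol=5e-4)

    def test_negative_time_rejected(self):
        dist = ParametricSurvival("exponential", (0.1,))
        with pytest.raises(ValueError):
            dist.survival(-1.0)

    def test_negative_gompertz_shape_plateaus(self):
        dist = ParametricSurvival("gompertz", (-0.1, 0.05))
        s = dist.survival(np.array([0.0, 1000.0, 5000.0]))
        assert s[0] == 1.0
        assert math.isclose(s[1], math.exp(-0.05 / 0.1), rel_tol=1e-3)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvival("lognormal", (1.0, -0.5))
        with pytest.raises(ValueError):
            ParametricSurvival("weibull", (0.0, 1.0))
        with pytest.raises(ValueError):
            ParametricSurvival("normalish", (1.0,))


class TestFitting:
    def test_exponential_closed_form_mle(self):
        # events at 1, 2, 3 months, none censored: rate = 3 events / 6 months
        fm = fit_parametric([1.0, 2.0, 3.0], [1, 1, 1], "exponential")
        assert math.isclose(fm.dist.params[0], 0.5, rel_tol=1e-6)
        expected_ll = 3 * math.log(0.5) - 0.5 * 6
        assert math.isclose(fm.loglik, expected_ll, rel_tol=1e-9)
        assert fm.aic == pytest.approx(2 - 2 * expected_ll)
        assert fm.bic == pytest.approx(math.log(3) - 2 * expected_ll)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_within_3_se(self, family):
        """MLE on simulated data recovers the truth within 3 reported SEs."""
        truth = EXAMPLES[family]
        dist = ParametricSurvival(family, truth)
        t, e = simulate_censored(dist, n=2000, seed=11, cens_frac=0.3)
        fm = fit_parametric(t, e, family)
        for est, tr, se in zip(fm.dist.params, truth, fm.dist.param_se):
            assert np.isfinite(se) and se > 0
            assert abs(est - tr) <= 3 * se, (family, est, tr, se)

    def test_all_censored_fails(self):
        with pytest.raises(FitError, match="no events"):
            fit_parametric([1.0, 2.0], [0, 0], "weibull")

    def test_agrees_with_lifelines(self):
        """Independent MLE cross-check on the same censored sample."""
        from lifelines import LogNormalFitter, WeibullFitter

        dist = ParametricSurvival("lognormal", (2.2773, 1.13))
        t, e = simulate_censored(dist, n=800, seed=5)
        ours = fit_parametric(t, e, "lognormal")
        ll = LogNormalFitter().fit(t, e)
        assert ours.dist.params[0] == pytest.approx(ll.mu_, rel=1e-4)
        assert ours.dist.params[1] == pytest.approx(ll.sigma_, rel=1e-4)
        assert ours.dist.param_se[0] == pytest.approx(
            float(ll.summary.loc["mu_", "se(coef)"]), rel=1e-2
        )
        ours_w = fit_parametric(t, e, "weibull")
        lw = WeibullFitter().fit(t, e)
        assert ours_w.dist.params[0] == pytest.approx(lw.rho_, rel=1e-3)
        assert ours_w.dist.params[1] == pytest.approx(lw.lambda_, rel=1e-3)


class TestSelection:
    @staticmethod
    def _fm(family, aic, bic):
        return FittedModel(
            dist=ParametricSurvival(family, EXAMPLES[family]),
            loglik=0.0, aic=aic, bic=bic, n=10, n_events=5,
        )

    def test_lowest_aic_wins(self):
        models = [
            self._fm("exponential", 100, 101),
            self._fm("lognormal", 90, 93),
            self._fm("weibull", 95, 96),
        ]
        rep = select_best(models)
        assert rep.best_aic == "lognormal"
        assert rep.table[0][0] == "lognormal"

    def test_aic_tie_broken_by_bic(self):
        models = [self._fm("weibull", 90, 95), self._fm("lognormal", 90, 93)]
        assert select_best(models).best_aic == "lognormal"

    def test_disagreement_flagged(self):
        models = [self._fm("weibull", 90, 99), self._fm("lognormal", 91, 92)]
        rep = select_best(models)
        assert rep.best_aic == "weibull"
        assert rep.best_bic == "lognormal"
        assert not rep.agreement

    def test_needs_two_candidates(self):
        with pytest.raises(ValueError):
            select_best([self._fm("weibull", 90, 95)])


class TestHybridCurve:
    km = StepCurve(times=(0.0, 2.0, 5.0, 9.0), probs=(1.0, 0.8, 0.55, 0.4))
    dist = ParametricSurvival("lognormal", (2.0, 1.0))

    def test_km_section_is_exact(self):
        h = build_hybrid_curve(self.km, self.dist, cutoff=9.0)
        for t in (0.0, 1.9, 2.0, 5.0, 8.99):
            assert float(h(t)) == float(self.km(t))

    def test_continuity_at_cutoff(self):
        h = build_hybrid_curve(self.km, self.dist, cutoff=9.0)
        left = float(h(9.0))
        right = float(h(9.0 + 1e-9))
        assert math.isclose(left, right, abs_tol=1e-6)

    def test_identity_when_km_equals_parametric(self):
        par = ParametricCurve(self.dist)
        h = build_hybrid_curve(par, self.dist, cutoff=6.0)
        grid = np.linspace(0, 60, 121)
        assert np.allclose(h(grid), par(grid), atol=1e-12)

    def test_degenerate_tail_rejected(self):
        dist = ParametricSurvival("weibull", (3.0, 1.0))  # S(40) underflows to 0
        with pytest.raises(ValueError, match="degenerate"):
            build_hybrid_curve(self.km, dist, cutoff=40.0)


class TestDiscountedStateTime:
    def test_unit_survival_one_year(self):
        assert discounted_state_time(lambda t: np.ones_like(t), 1.0, 0.0, 1 / 12) == pytest.approx(1.0)

    def test_exponential_closed_form(self):
        """Trapezoid result within 0.1% of the analytic discounted integral."""
        lam_y = 0.9  # per year
        rate = 0.03
        curve = ParametricCurve(ParametricSurvival("exponential", (lam_y / 12,)))
        rho = math.log(1 + rate)
        expected = (1 - math.exp(-(lam_y + rho) * 10)) / (lam_y + rho)
        got = discounted_state_time(curve, 10.0, rate, 1 / 12)
        assert abs(got - expected) / expected < 1e-3

    def test_discounting_reduces_person_time(self, config):
        curve = ParametricCurve(config.strategy("ivosidenib").os)
        assert discounted_state_time(curve, 10, 0.03, 1 / 12) < discounted_state_time(
            curve, 10, 0.0, 1 / 12
        )

    def test_grid_convergence_on_shipped_curves(self, config):
        """Halving the cycle length moves the result by < 0.05%."""
        for s in config.strategies:
            for dist in (s.os, s.pfs):
                curve = ParametricCurve(dist)
                coarse = discounted_state_time(curve, 10, 0.03, 1 / 12)
                fine = discounted_state_time(curve, 10, 0.03, 1 / 24)
                assert abs(coarse - fine) / fine < 5e-4


@settings(max_examples=25, deadline=None)
@given(
    meanlog=st.floats(0.5, 3.0),
    sdlog=st.floats(0.3, 1.5),
    t=st.floats(0.0, 200.0),
)
def test_lognormal_survival_matches_normal_cdf(meanlog, sdlog, t):
    """Property: S(t) = 1 - Phi((ln t - mu)/sigma) for every input."""
    dist = ParametricSurvival("lognormal", (meanlog, sdlog))
    expected = 1.0 if t == 0 else stats.norm.sf((math.log(t) - meanlog) / sdlog)
    assert math.isclose(float(dist.survival(t)), expected, abs_tol=1e-12)
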