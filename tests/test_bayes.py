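"""Priors, the Lindley engine, the quadrature oracle, and loss estimators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import digamma

import mwedist as mw
from mwedist.bayes import HFunction, Moments, QuadratureError


class TestPrior:
    def test_elicitation_identity(self):
        g = mw.elicit_prior([2.0, 2.0, 2.0], rates=[1.0, 1.0, 1.0])
        assert g.shapes == (2.0, 2.0, 2.0)
        g = mw.elicit_prior([0.1, 0.5, 0.1])
        assert g.shapes == pytest.approx((0.1, 0.5, 0.1))
        np.testing.assert_allclose(g.means, [0.1, 0.5, 0.1], rtol=1e-15)

    def test_flat_prior_gradient_zero(self, unit_params):
        g = mw.GammaPriorSpec.flat()
        np.testing.assert_array_equal(mw.log_prior_gradient(unit_params, g), 0.0)

    def test_gradient_zero_at_prior_mode(self):
        g = mw.GammaPriorSpec((2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        np.testing.assert_allclose(
            mw.log_prior_gradient(mw.Params(1.0, 1.0, 1.0), g), 0.0, atol=1e-15
        )

    def test_gradient_matches_finite_difference(self):
        g = mw.GammaPriorSpec((2.5, 0.8, 1.7), (1.2, 0.4, 2.0))
        p = np.array([0.7, 1.9, 0.45])
        grad = mw.log_prior_gradient(mw.Params.from_array(p), g)
        for j in range(3):
            h = 1e-7
            pp, pm = p.copy(), p.copy()
            pp[j] += h
            pm[j] -= h
            num = (g.log_density(*pp) - g.log_density(*pm)) / (2 * h)
            assert grad[j] == pytest.approx(num, abs=1e-7)

    def test_validation(self):
        with pytest.raises(ValueError):
            mw.elicit_prior([1.0, -1.0, 1.0])
        with pytest.raises(ValueError):
            mw.GammaPriorSpec((0.0, 1.0, 1.0), (1.0, 1.0, 1.0))


class TestLindleyEngine:
    def test_linear_h_flat_prior_zero_third_returns_mle(self):
        S = np.diag([0.1, 0.2, 0.3])
        b = mw.DerivativeBundle(
            mle=mw.Params(1.5, 0.7, 2.1),
            hessian=-np.linalg.inv(S),
            third=np.zeros((3, 3, 3)),
            S=S,
            rho=np.zeros(3),
        )
        h = HFunction(1.5, [1.0, 0.0, 0.0], np.zeros((3, 3)))
        assert mw.lindley_expectation(h, b) == 1.5

    def test_exact_for_gamma_means(self):
        # with a product-gamma 'log-likelihood' the Lindley expansion of the
        # posterior mean is exact in every coordinate
        alpha = np.array([5.0, 3.0, 7.0])
        beta = np.array([2.0, 1.0, 3.0])
        mode = (alpha - 1.0) / beta
        b = mw.derivative_bundle(
            None,
            mw.Params.from_array(mode),
            gradient_fn=lambda v: (alpha - 1.0) / v - beta,
        )
        for j in range(3):
            h = HFunction(mode[j], np.eye(3)[j], np.zeros((3, 3)))
            assert mw.lindley_expectation(h, b) == pytest.approx(alpha[j] / beta[j], rel=1e-6)

    def test_agrees_with_quadrature_when_well_identified(self, fitted_1000, unit_prior):
        s, fit, b = fitted_1000
        lin = mw.lindley_moments(b)
        quad = mw.quadrature_moments(s, unit_prior, bundle=b)
        for name in ("theta", "sigma", "mu"):
            for kind in ("m1", "m2", "inv1", "inv2"):
                lv, qv = getattr(lin[name], kind), getattr(quad[name], kind)
                assert lv == pytest.approx(qv, rel=0.12), (name, kind)
            # log-moments sit near zero: compare absolutely
            assert lin[name].ln == pytest.approx(quad[name].ln, abs=0.08)
        # the well-identified sigma coordinate is in the asymptotic regime
        for kind in ("m1", "m2", "inv1", "inv2"):
            assert getattr(lin["sigma"], kind) == pytest.approx(
                getattr(quad["sigma"], kind), rel=0.03
            )

    def test_posterior_variance_positive(self, fitted_1000):
        _, _, b = fitted_1000
        lin = mw.lindley_moments(b)
        for name in ("theta", "sigma", "mu"):
            assert lin[name].m2 - lin[name].m1 ** 2 > 0


class TestQuadrature:
    def test_unit_function_integrates_to_one(self, fitted_1000, unit_prior):
        s, _, b = fitted_1000
        val = mw.quadrature_posterior_expectation(
            lambda th, sg, mu: np.ones_like(th), s, unit_prior, bundle=b, nodes=24
        )
        assert val == pytest.approx(1.0, rel=1e-12)

    def test_grid_refinement_stability(self, fitted_1000, unit_prior):
        s, _, b = fitted_1000
        coarse = mw.quadrature_moments(s, unit_prior, bundle=b, nodes=64)
        fine = mw.quadrature_moments(s, unit_prior, bundle=b, nodes=81)
        assert coarse["theta"].m1 == pytest.approx(fine["theta"].m1, rel=1e-3)
        assert coarse["theta"].inv2 == pytest.approx(fine["theta"].inv2, rel=1e-3)

    def test_bernstein_von_mises_large_n(self, fitted_1000, unit_prior):
        s, fit, b = fitted_1000
        post_mean = mw.quadrature_posterior_expectation(
            lambda th, sg, mu: sg, s, unit_prior, bundle=b, nodes=48
        )
        assert abs(post_mean - fit.params.sigma) <= 2.0 * b.se[1]

    def test_heavy_ridge_posteriors_are_refused(self, unit_params, unit_prior):
        # weakly identified samples put moment mass on the box boundary; the
        # pipeline must refuse (nonexistent MLE or boundary mass) rather than
        # return a truncated integral, and must do so for some small samples
        refused = 0
        for seed in range(100, 112):
            s = mw.generate_censored_sample(50, 40, unit_params, seed=seed)
            try:
                fit = mw.fit_mle(s)
                b = mw.derivative_bundle(
                    s, fit.params,
                    prior_gradient=mw.log_prior_gradient(fit.params, unit_prior),
                )
                mw.quadrature_moments(s, unit_prior, bundle=b)
            except (QuadratureError, mw.FitError, mw.InformationMatrixError):
                refused += 1
        assert refused > 0


GAMMA32 = Moments(
    m1=1.5, m2=3.0, inv1=1.0, inv2=2.0, ln=float(digamma(3.0) - np.log(2.0))
)


class TestLossEstimators:
    def test_gamma_closed_forms(self):
        expect = {
            "SELF": (1.5, 0.75),
            "PLF": (np.sqrt(3.0), 2 * (np.sqrt(3.0) - 1.5)),
            "QLF": (0.5, 0.5),
            "ELF": (1.0, float(digamma(3.0) - np.log(2.0))),
        }
        for loss, (est, risk) in expect.items():
            got = mw.estimator_from_moments(loss, GAMMA32)
            assert got.estimate == pytest.approx(est, rel=1e-12)
            assert got.posterior_risk == pytest.approx(risk, rel=1e-12)
            assert got.risk_valid

    def test_degenerate_point_mass(self):
        c = 0.73
        m = Moments(m1=c, m2=c**2, inv1=1 / c, inv2=1 / c**2, ln=float(np.log(c)))
        for loss in ("SELF", "PLF", "QLF", "ELF"):
            got = mw.estimator_from_moments(loss, m)
            assert got.estimate == pytest.approx(c, rel=1e-12)
            assert got.posterior_risk == pytest.approx(0.0, abs=1e-12)

    def test_incoherent_moments_flagged_not_clipped(self):
        bad = Moments(m1=2.0, m2=3.0, inv1=0.6, inv2=0.5, ln=0.5)  # m2 < m1^2
        got = mw.estimator_from_moments("SELF", bad)
        assert got.estimate == 2.0
        assert not got.risk_valid
        assert got.posterior_risk < 0  # reported as-is

    def test_unknown_loss(self):
        with pytest.raises(ValueError):
            mw.estimator_from_moments("L2", GAMMA32)

    @given(
        a=st.floats(min_value=2.5, max_value=40.0),
        b=st.floats(min_value=0.1, max_value=20.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_ordering_for_exact_gamma_posteriors(self, a, b):
        # QLF <= ELF <= SELF <= PLF for any coherent (true-posterior) moments
        m = Moments(
            m1=a / b,
            m2=a * (a + 1) / b**2,
            inv1=b / (a - 1),
            inv2=b**2 / ((a - 1) * (a - 2)),
            ln=float(digamma(a) - np.log(b)),
        )
        assert m.coherent
        vals = [
            mw.estimator_from_moments(loss, m).estimate
            for loss in ("QLF", "ELF", "SELF", "PLF")
        ]
        assert vals == sorted(vals)
        for loss in ("QLF", "ELF", "SELF", "PLF"):
            est = mw.estimator_from_moments(loss, m)
            assert est.risk_valid and est.posterior_risk >= 0


class TestBayesEstimates:
    def test_flat_prior_large_n_collapses_to_mle(self, unit_params):
        s = mw.generate_censored_sample(2000, 1600, unit_params, seed=42)
        fit = mw.fit_mle(s)
        bundle = mw.derivative_bundle(s, fit.params)  # zero prior gradient
        est = mw.bayes_estimates(s, mw.GammaPriorSpec.flat(), bundle=bundle)
        for loss in ("SELF", "PLF", "QLF", "ELF"):
            assert est["sigma"][loss].estimate == pytest.approx(fit.params.sigma, rel=0.05)
        b2 = mw.derivative_bundle(s, fit.params)
        assert abs(est["theta"]["SELF"].estimate - fit.params.theta) <= b2.se[0]

    def test_lindley_vs_quadrature_route(self, fitted_1000, unit_prior):
        s, _, b = fitted_1000
        lind = mw.bayes_estimates(s, unit_prior, bundle=b, method="lindley")
        quad = mw.bayes_estimates(s, unit_prior, bundle=b, method="quadrature")
        for loss in ("SELF", "ELF"):
            assert lind["sigma"][loss].estimate == pytest.approx(
                quad["sigma"][loss].estimate, rel=0.03
            )
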