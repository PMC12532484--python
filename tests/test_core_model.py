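"""Likelihood, link, preprocessing, and design-matrix behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from extbeta.core_model import (
    CSType,
    ModelSpec,
    OrderedBetaParams,
    Phase,
    Rating,
    TrialRecord,
    build_linear_predictor,
    expected_rating,
    logistic,
    ordered_beta_logdensity,
    preprocess_ratings,
)


class TestLogistic:
    def test_symmetry_and_saturation(self):
        assert logistic(0.0) == 0.5
        assert 1 - 1e-15 < logistic(40.0) <= 1.0
        assert logistic(700.0) == 1.0  # stable at large argument

    @pytest.mark.parametrize("z", [-3.0, -1.0, 0.7, 5.0])
    def test_reflection_identity(self, z):
        assert logistic(z) + logistic(-z) == pytest.approx(1.0, abs=1e-15)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            logistic(float("nan"))
        with pytest.raises(ValueError):
            logistic(float("inf"))

    @given(st.floats(-500, 500), st.floats(-500, 500))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if hi - lo > 1e-9:
            assert logistic(lo) <= logistic(hi)


class TestPreprocess:
    def test_stated_rule(self):
        out = preprocess_ratings([0, 50, 100])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(50 / 101)
        assert out[2] == pytest.approx(100 / 101)
        assert np.all(out < 1.0)

    def test_rejects_out_of_range_naming_position(self):
        with pytest.raises(ValueError, match="position 2"):
            preprocess_ratings([3, 7, 101])

    def test_injective_and_order_preserving(self):
        out = preprocess_ratings(np.arange(101))
        assert len(np.unique(out)) == 101
        assert np.all(np.diff(out) > 0)


class TestOrderedBetaDensity:
    def test_zero_branch_at_threshold(self):
        # zeta == gamma puts half the mass on zero
        p = OrderedBetaParams(zeta=1.3, gamma=1.3, phi=0.7)
        assert ordered_beta_logdensity(0.0, p) == pytest.approx(math.log(0.5))

    def test_uniform_beta_case(self):
        # mu = 0.5, tau = 2 gives Beta(1,1); with no zero inflation the
        # continuous density is 1 everywhere
        p = OrderedBetaParams(zeta=0.0, gamma=-40.0, phi=math.log(2.0))
        assert ordered_beta_logdensity(0.3, p) == pytest.approx(0.0, abs=1e-12)

    def test_rejects_unit_boundary(self):
        p = OrderedBetaParams(zeta=0.0, gamma=0.0, phi=0.0)
        with pytest.raises(ValueError):
            ordered_beta_logdensity(1.0, p)
        with pytest.raises(ValueError):
            ordered_beta_logdensity(-0.01, p)

    def test_normalization_by_quadrature(self):
        # point mass at zero plus the continuous branch must integrate to 1;
        # tanh-sinh quadrature (mpmath) handles the mildly singular Beta
        # endpoints.  Parameters are drawn in the regime where both Beta
        # shapes stay >= ~0.8 so the density is integrable to high accuracy.
        import mpmath

        rng = np.random.default_rng(42)
        for _ in range(20):
            p = OrderedBetaParams(
                zeta=float(rng.uniform(-1.3, 1.3)),
                gamma=float(rng.normal(0, 2)),
                phi=float(rng.uniform(math.log(4.0), 3.0)),
            )
            def integrand(y):
                yf = float(y)
                if yf <= 0.0 or yf >= 1.0:  # open-interval endpoints
                    return 0.0
                return math.exp(ordered_beta_logdensity(yf, p))

            cont = float(mpmath.quad(integrand, [0, 1]))
            total = (1 - p.theta) + cont
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_zero_probability_monotonic_in_zeta_and_gamma(self):
        zs = np.linspace(-4, 4, 30)
        pz = [1 - OrderedBetaParams(z, 0.5, 0.0).theta for z in zs]
        assert np.all(np.diff(pz) < 0)
        pg = [1 - OrderedBetaParams(0.5, g, 0.0).theta for g in zs]
        assert np.all(np.diff(pg) > 0)

    def test_variance_decreases_with_phi(self):
        # Beta branch variance mu(1-mu)/(1+tau) shrinks as phi grows
        def branch_var(phi):
            mu, tau = 0.4, math.exp(phi)
            a, b = mu * tau, (1 - mu) * tau
            return stats.beta(a, b).var()

        vs = [branch_var(p) for p in [0.0, 1.0, 2.0, 3.0]]
        assert np.all(np.diff(vs) < 0)


class TestExpectedRating:
    def test_analytic_cases(self):
        assert expected_rating(OrderedBetaParams(0.0, 0.0, 0.0)) == pytest.approx(0.25)
        p = OrderedBetaParams(1.2, -40.0, 1.0)
        assert expected_rating(p) == pytest.approx(logistic(1.2), abs=1e-12)

    def test_matches_monte_carlo(self):
        # fitted-scale parameters: intercept 1.88, threshold 2.35
        p = OrderedBetaParams(zeta=1.88, gamma=2.35, phi=math.log(5.0))
        rng = np.random.default_rng(7)
        n = 10**6
        tau = p.precision
        draws = np.where(
            rng.random(n) < p.theta,
            rng.beta(p.mu * tau, (1 - p.mu) * tau, size=n),
            0.0,
        )
        se = draws.std() / math.sqrt(n)
        assert abs(draws.mean() - expected_rating(p)) < 3 * se


def _record(trial=3, cs=CSType.CS_PLUS, moderators=None):
    return TrialRecord(
        participant_id="P001",
        phase=Phase.EXTINCTION,
        trial_index=trial,
        cs_type=cs,
        reinforced=False,
        rating=Rating(40),
        moderators=moderators or {},
    )


class TestLinearPredictor:
    def test_all_zero_coefficients(self):
        spec = ModelSpec.named("baseline")
        z = build_linear_predictor(
            _record(), spec, {"intercept": 0.0, "trial": 0.0}, {"P001": (0.0, 0.0)}, {3: 0.0}
        )
        assert z == 0.0

    def test_intercept_only(self):
        spec = ModelSpec(fixed_terms=("intercept",))
        z = build_linear_predictor(
            _record(), spec, {"intercept": 1.88}, {"P001": (0.0, 0.0)}, {3: 0.0}
        )
        assert z == pytest.approx(1.88)

    def test_hand_computed_dot_product(self):
        spec = ModelSpec.named("acquisition")
        fixed = {"intercept": 1.0, "trial": -0.2, "cs_type": 2.0, "trial_x_cs": 0.1}
        z = build_linear_predictor(
            _record(trial=4), spec, fixed, {"P001": (0.3, -0.05)}, {4: 0.07}
        )
        # 1 + (-0.2)(4) + 2(0.5) + 0.1(4)(0.5) + 0.3 + (-0.05)(4) + 0.07
        assert z == pytest.approx(1.0 - 0.8 + 1.0 + 0.2 + 0.3 - 0.2 + 0.07)

    def test_missing_moderator_raises(self):
        spec = ModelSpec.named("moderated", moderator="iu_total")
        fixed = {"intercept": 0, "trial": 0, "moderator": 1.0, "trial_x_moderator": 0.5}
        with pytest.raises(ValueError, match="moderator"):
            build_linear_predictor(_record(), spec, fixed, {"P001": (0, 0)}, {3: 0})


class TestDomainTypes:
    def test_rating_invariants(self):
        assert Rating(0).unit == 0.0
        assert Rating(100).unit == pytest.approx(100 / 101)
        with pytest.raises(ValueError):
            Rating(101)

    def test_trial_record_constraints(self):
        with pytest.raises(ValueError):
            TrialRecord("P", Phase.ACQUISITION, 0, CSType.CS_MINUS, True, Rating(0))
        with pytest.raises(ValueError):
            TrialRecord("P", Phase.EXTINCTION, 0, CSType.CS_PLUS, True, Rating(0))
        r = TrialRecord("P", Phase.ACQUISITION, 0, CSType.CS_PLUS, True, Rating(50), spider_path=2)
        assert r.cs_code == 0.5

    def test_model_spec_validation(self):
        with pytest.raises(ValueError):
            ModelSpec(fixed_terms=("intercept", "trial_x_moderator"), moderator_name="iu_total")
        with pytest.raises(ValueError):
            ModelSpec(fixed_terms=("intercept", "moderator"))  # no moderator name
        spec = ModelSpec.named("linear")
        assert spec.family == "linear_normal"
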