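"""Core model: parameter presets, production inputs, vector field, Jacobian."""

import numpy as np
import pytest

from klkbarrier.model import (
    ConfigurationError,
    ModelState,
    ValidationError,
    build_parameters,
    half_life_minutes,
    jacobian,
    klk5_production,
    lekti_production,
    rhs,
    simulate,
)


class TestBuildParameters:
    def test_hc_nominal_values(self):
        p = build_parameters("HC", 1, {})
        expected = dict(kon=1, koff=1, kA=10, rhoL=1, bP=10, bL=1, bK=0,
                        kappaK=0.5, kappaL=0.05, deltaL=0.5, deltaK=1,
                        deltaP=0.5, mK=50)
        for name, value in expected.items():
            assert getattr(p, name) == value, name

    def test_ad_ph_uses_high_ph_rates(self):
        p = build_parameters("AD-pH", 1, {})
        assert (p.kon, p.kA, p.rhoL) == (3.0, 50.0, 1.0)
        assert p.koff > p.kon  # complex dissociates much faster at pH 6.5

    def test_ad_lekti_variant2(self):
        p = build_parameters("AD-LEKTI", 2, {})
        assert (p.rhoL, p.kA, p.kI, p.kappaL) == (0.5, 10.0, 5.0, 0.0)

    @pytest.mark.parametrize("dependent,source", [
        ("kP", "kA"), ("mP", "mK"), ("deltaKact", "deltaK"),
        ("deltaPact", "deltaP"),
    ])
    def test_equality_ties_follow_overridden_source(self, dependent, source):
        p = build_parameters("HC", 1, {source: 7.0})
        assert getattr(p, dependent) == 7.0

    def test_explicit_override_breaks_tie(self):
        p = build_parameters("HC", 1, {"deltaKact": 0.2})
        assert p.deltaKact == 0.2 and p.deltaK == 1.0

    def test_unknown_condition_and_parameter(self):
        with pytest.raises(ConfigurationError):
            build_parameters("AD", 1, {})
        with pytest.raises(ConfigurationError):
            build_parameters("HC", 1, {"kappa": 1.0})

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            build_parameters("HC", 1, {"kon": -1.0})


class TestProductionInputs:
    def test_klk5_zero_without_stimulus_or_feedback(self, hc1):
        assert klk5_production(0.0, 0.0, hc1) == 0.0

    def test_klk5_stimulus_term(self, hc1):
        assert klk5_production(1.0, 0.0, hc1) == pytest.approx(0.5)

    def test_klk5_linear_feedback(self, hc1):
        assert klk5_production(1.0, 2.0, hc1) == pytest.approx(
            0.5 * 1.0 + 0.5 * 2.0
        )

    def test_klk5_increasing_in_pact(self, hc1):
        lo, hi = (klk5_production(1.0, x, hc1) for x in (0.0, 5.0))
        assert hi > lo

    def test_lekti_basal(self):
        hc = build_parameters("HC", 1, {})
        ad = build_parameters("AD-LEKTI", 1, {})
        assert lekti_production(0.0, 0.0, hc) == pytest.approx(1.0)
        # limited LEKTI production: exactly half the HC output
        assert lekti_production(0.0, 0.0, ad) == pytest.approx(0.5)

    def test_variant_contract(self):
        """Variant 1 never below, variant 2 never above, its Pact=0 level."""
        v1 = build_parameters("HC", 1, {})
        v2 = build_parameters("HC", 2, {})
        for pact in (0.5, 2.0, 50.0):
            assert lekti_production(1.0, pact, v1) >= lekti_production(1.0, 0.0, v1)
            assert lekti_production(1.0, pact, v2) <= lekti_production(1.0, 0.0, v2)

    def test_variant2_inhibition_floor(self):
        v2 = build_parameters("HC", 2, {})
        huge = lekti_production(0.0, 1e9, v2)
        assert 0.0 < huge < lekti_production(0.0, 0.0, v2)
        assert huge == pytest.approx(0.0, abs=1e-6)

    def test_negative_inputs_rejected(self, hc1):
        with pytest.raises(ValidationError):
            klk5_production(-1.0, 0.0, hc1)
        with pytest.raises(ValidationError):
            lekti_production(0.0, -1.0, hc1)


class TestVectorField:
    def test_all_zero_state_only_production_survives(self, hc1):
        d = rhs(np.zeros(6), hc1.with_(mu=0.0))
        np.testing.assert_allclose(d, [1.0, 0.0, 0.0, 0.0, 10.0, 0.0])

    def test_association_flux_stoichiometry(self, hc1):
        """kon*L*Kact leaves L and Kact, enters C, with unit coefficients."""
        y = np.array([2.0, 3.0, 1.5, 0.7, 4.0, 1.0])
        base = rhs(y, hc1)
        bumped = rhs(y, hc1.with_(kon=hc1.kon + 1.0))
        flux_delta = y[0] * y[2]  # d(kon)*L*Kact
        np.testing.assert_allclose(
            bumped - base,
            [-flux_delta, 0.0, -flux_delta, flux_delta, 0.0, 0.0],
            atol=1e-12,
        )

    def test_zero_inflammation_steady_state_residual(self, hc1_nofeedback):
        from klkbarrier.steady import zero_activation_state

        s = zero_activation_state(hc1_nofeedback.with_(mu=0.0))
        assert np.max(np.abs(rhs(s, hc1_nofeedback.with_(mu=0.0)))) < 1e-10

    def test_klk5_lineage_flux_balance(self, hc1):
        """d(K+Kact+C)/dt = f_K - deltaK*K - deltaKact*Kact - deltaC*C."""
        p = hc1.with_(mu=2.0)
        y = np.array([1.0, 4.0, 2.0, 0.5, 8.0, 3.0])
        d = rhs(y, p)
        lineage = d[1] + d[2] + d[3]
        expected = (
            klk5_production(p.mu, y[5], p)
            - p.deltaK * y[1] - p.deltaKact * y[2] - p.deltaC * y[3]
        )
        assert lineage == pytest.approx(expected, rel=1e-12)


class TestJacobian:
    def test_matches_finite_differences(self, hc1, rng):
        p = hc1.with_(mu=1.5)
        h = 1e-6
        worst = 0.0
        for _ in range(100):
            y = rng.uniform(0.1, 20.0, size=6)
            J = jacobian(y, p)
            for j in range(6):
                e = np.zeros(6)
                e[j] = h * max(1.0, abs(y[j]))
                fd = (rhs(y + e, p) - rhs(y - e, p)) / (2 * e[j])
                scale = np.maximum(np.abs(J[:, j]), 1.0)
                worst = max(worst, np.max(np.abs(J[:, j] - fd) / scale))
        assert worst < 1e-6

    def test_dPdt_wrt_P_at_zero_activation(self, hc1):
        """With no active KLK5 and no stimulus only degradation remains."""
        y = np.array([2.0, 3.0, 0.0, 0.5, 7.0, 1.0])
        J = jacobian(y, hc1.with_(mu=0.0))
        assert J[4, 4] == pytest.approx(-hc1.deltaP)

    def test_dKactdt_wrt_K_at_origin_of_K(self, hc1):
        y = np.array([2.0, 0.0, 3.0, 0.5, 7.0, 1.0])
        J = jacobian(y, hc1)
        assert J[2, 1] == pytest.approx(hc1.kA * y[2] / hc1.mK)


class TestSimulate:
    def test_fixed_point_stays_fixed(self, hc1_nofeedback):
        from klkbarrier.steady import zero_activation_state

        p = hc1_nofeedback.with_(mu=0.0)
        s = zero_activation_state(p)
        traj = simulate(p, s, np.linspace(0, 50, 101))
        np.testing.assert_allclose(traj.y, np.tile(s.to_array(), (101, 1)),
                                   atol=1e-7)

    def test_perturbed_stable_state_returns(self, hc1):
        """A stable ignited state reattracts a 1% perturbation."""
        from klkbarrier.steady import STABLE, find_steady_states

        p = hc1.with_(mu=5.0, alphaK=1.0, alphaL=0.0)
        stable = [s for s in find_steady_states(p) if s.stability == STABLE]
        high = max(stable, key=lambda s: s.Pact)
        y0 = high.state.to_array() * 1.01
        traj = simulate(p, y0, np.linspace(0, 200, 51))
        np.testing.assert_allclose(traj.y[-1], high.state.to_array(), rtol=1e-5)

    def test_nonnegativity_from_origin(self, hc1):
        traj = simulate(hc1.with_(mu=1.0), np.zeros(6), np.linspace(0, 100, 201))
        assert traj.y.min() > -1e-8

    def test_bp_scales_basal_par2_level(self, hc1_nofeedback):
        """Doubling bP doubles the basal P steady level bP/deltaP."""
        from klkbarrier.steady import zero_activation_state

        p = hc1_nofeedback.with_(mu=0.0)
        s1 = zero_activation_state(p)
        s2 = zero_activation_state(p.with_(bP=2 * p.bP))
        assert s2.P == pytest.approx(2 * s1.P)
        assert s1.P == pytest.approx(p.bP / p.deltaP)

    def test_bad_time_grid_rejected(self, hc1):
        with pytest.raises(ValidationError):
            simulate(hc1, np.zeros(6), [0.0, 0.0, 1.0])


class TestHalfLife:
    @pytest.mark.parametrize("rate,minutes", [(1.0, 15.0), (0.5, 30.0), (0.2, 75.0)])
    def test_calibrated_conversion(self, rate, minutes):
        assert half_life_minutes(rate) == pytest.approx(minutes)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            half_life_minutes(0.0)


class TestModelState:
    def test_round_trip(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert ModelState.from_array(y).to_array() is not y
        np.testing.assert_array_equal(ModelState.from_array(y).to_array(), y)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            ModelState(1, 1, -0.1, 1, 1, 1)
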