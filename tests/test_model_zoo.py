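import math

import numpy as np
import pytest

from stateresp.core_model import PopulationState, fast_vector_field, validate_consistency
from stateresp.fast_equilibrium import solve_nonlinear
from stateresp.model_zoo import (
    ZOO_BUILDERS,
    dd_handling,
    dd_handling_closed_forms,
    experience,
    experience_closed_forms,
    holling_bd_mappings,
    panic,
    panic_closed_forms,
    starvation,
    starvation_closed_forms,
    tiered_prey,
    two_state_prey,
    two_state_prey_closed_forms,
    two_state_prey_f_as_printed,
)

SQRT2 = math.sqrt(2.0)

ALL_BUILDERS = [
    lambda: tiered_prey(3, [1.0, 2.0], [0.5, 0.8], [1.0, 2.0, 3.0], 1.5),
    lambda: two_state_prey(2.0, 0.5, 10.0, 15.0, 1.0),
    lambda: dd_handling(50.0, 2.0, 1.0),
    lambda: starvation(10.0, 0.2, 4.0, 3.0, 10.0, 2.0, 0.2, 0.5),
    lambda: experience(10.0, 0.2, 4.0, 3.0),
    lambda: panic(1.0, 0.2, 10.0, 1.0),
]


@pytest.mark.parametrize("builder", ALL_BUILDERS)
def test_builders_emit_consistent_models(builder):
    zm = builder()
    assert validate_consistency(zm.model).ok


@pytest.mark.parametrize("builder", ALL_BUILDERS)
def test_closed_equilibrium_annihilates_fast_field(builder):
    zm = builder()
    for X, Y in [(0.3, 1.2), (2.0, 0.5), (7.0, 3.0)]:
        x_hat, y_hat = zm.closed_equilibrium(X, Y)
        state = PopulationState(x=x_hat, y=y_hat)
        dx, dy = fast_vector_field(zm.model, state)
        resid = max(np.abs(dx).max(), np.abs(dy).max())
        assert resid < 1e-10 * max(1.0, X + Y)


class TestTieredPrey:
    def test_m1_is_holling2(self):
        zm = tiered_prey(1, [], [], [1.0], 1.0)
        assert zm.closed_f(1.0, 1.0) == pytest.approx(0.5)

    def test_m1_independent_of_Y(self):
        zm = tiered_prey(1, [], [], [2.0], 3.0)
        assert zm.closed_f(1.7, 0.1) == zm.closed_f(1.7, 9.0)

    def test_saturates_at_d(self, two_state_up):
        assert two_state_up.closed_f(1e8, 2.0) == pytest.approx(1.0, abs=1e-6)

    def test_rejects_zero_return_rate(self):
        with pytest.raises(ValueError):
            tiered_prey(2, [0.0], [1.0], [1.0, 1.0], 1.0)

    def test_m2_equals_two_state_closed_forms(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            A12, A1, c1, c2, d = rng.uniform(0.2, 5.0, 5)
            X, Y = rng.uniform(0.1, 10.0, 2)
            zm = tiered_prey(2, [A12], [A1], [c1, c2], d)
            x1, x2, f2 = two_state_prey_closed_forms(A12, A1, c1, c2, d, X, Y)
            assert zm.closed_f(X, Y) == pytest.approx(f2, rel=1e-12)
            x_hat, _ = zm.closed_equilibrium(X, Y)
            np.testing.assert_allclose(x_hat, [x1, x2], rtol=1e-12)


class TestTwoStatePrey:
    def test_no_predators_all_defended(self):
        x1, x2, f2 = two_state_prey_closed_forms(1.0, 1.0, 2.0, 3.0, 1.0, 4.0, 0.0)
        assert (x1, x2) == (4.0, 0.0)
        assert f2 == pytest.approx(8.0 / (1.0 + 8.0))

    def test_all_ones_hand_value(self):
        x1, x2, f2 = two_state_prey_closed_forms(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
        assert (x1, x2) == (0.5, 0.5)
        assert f2 == pytest.approx(0.5)

    def test_printed_form_differs_by_A12_factor(self):
        # the as-printed response carries a spurious A12 in the numerator
        args = (2.0, 0.5, 10.0, 15.0, 1.0, 3.0, 1.5)
        _, _, f_consistent = two_state_prey_closed_forms(*args)
        f_printed = two_state_prey_f_as_printed(*args)
        assert f_printed == pytest.approx(2.0 * f_consistent, rel=1e-12)

    def test_consistent_form_saturates_at_d(self):
        _, _, f2 = two_state_prey_closed_forms(2.0, 0.5, 10.0, 15.0, 1.0, 1e10, 2.0)
        assert f2 == pytest.approx(1.0, abs=1e-8)


class TestDDHandling:
    def test_zero_prey(self):
        s, h, f, gamma = dd_handling_closed_forms(50.0, 2.0, 1.0, 0.0)
        assert (s, h, f) == (1.0, 0.0, 0.0)
        assert gamma == pytest.approx(1.0)  # 1/d

    def test_hand_substitution(self):
        s, h, f, gamma = dd_handling_closed_forms(2.0, 1.0, 1.0, 1.0)
        assert (s, h) == (0.5, 0.5)
        assert f == pytest.approx(1.0)
        assert gamma == pytest.approx(0.5)

    def test_c2_zero_reduces_to_holling2(self):
        canon = holling_bd_mappings("holling2", {"c1": 3.0, "d": 2.0})
        for X in np.logspace(-2, 2, 10):
            _, _, f, _ = dd_handling_closed_forms(3.0, 0.0, 2.0, X)
            assert f == pytest.approx(canon.evaluate(X), rel=1e-12)


class TestStarvation:
    def test_all_ones_hand_values(self):
        cf = starvation_closed_forms(1, 1, 1, 1, 1, 1, 1, 1, 1.0)
        np.testing.assert_allclose(cf["equilibrium"], 0.25)
        assert cf["f"] == pytest.approx(0.5)
        assert cf["gamma"] == pytest.approx(1.0)
        assert cf["delta"] == pytest.approx(0.5)

    def test_ref_params_are_type3(self):
        cf = starvation_closed_forms(10, 0.2, 4, 3, 10, 2, 0.2, 0.5, 1.0)
        assert cf["is_type3"]  # c1/c2 = 50 > 1 + 3/4

    def test_ref_params_saturations(self):
        cf = starvation_closed_forms(10, 0.2, 4, 3, 10, 2, 0.2, 0.5, 1e8)
        assert cf["f"] == pytest.approx(4.0, abs=1e-6)        # d1
        assert cf["gamma_f"] == pytest.approx(10.0, abs=1e-5)  # Gamma1
        assert cf["gamma"] == pytest.approx(10.0 / 4.0, abs=1e-6)  # Gamma1/d1

    def test_ref_params_zero_prey_values(self):
        cf = starvation_closed_forms(10, 0.2, 4, 3, 10, 2, 0.2, 0.5, 0.0)
        assert cf["delta"] == pytest.approx(0.5)           # delta2
        assert cf["gamma"] == pytest.approx(2.0 / 4.0)     # Gamma2/d1 intercept

    def test_canonical_type3_mapping_identity(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            c1, c2, d1, d2 = rng.uniform(0.2, 5.0, 4)
            canon = holling_bd_mappings(
                "holling3", {"c1": c1, "c2": c2, "d1": d1, "d2": d2}
            )
            for X in np.logspace(-2, 2, 7):
                cf = starvation_closed_forms(c1, c2, d1, d2, 1, 1, 0, 0, X)
                assert canon.evaluate(X) == pytest.approx(cf["f"], rel=1e-12)

    def test_holling3_limit(self):
        # c2 -> 0, c1 -> inf with product fixed: f -> b X^2 / (1 + d X^2)
        K, d1, d2 = 2.0, 4.0, 3.0
        c2 = 1e-6
        c1 = K / c2
        b, d = K / d2, K / (d1 * d2)
        for X in (0.3, 1.0, 3.0):
            cf = starvation_closed_forms(c1, c2, d1, d2, 1, 1, 0, 0, X)
            limit = b * X * X / (1.0 + d * X * X)
            assert cf["f"] == pytest.approx(limit, rel=1e-4)


class TestExperience:
    def test_all_ones_hand_values(self):
        s1, s2, h = experience_closed_forms(1, 1, 1, 1, 1.0)
        assert (s1, s2, h) == (0.25, 0.25, 0.5)

    def test_searcher_fractions_match_starvation(self):
        for X in np.logspace(-1, 1, 5):
            s1, s2, _ = experience_closed_forms(10, 0.2, 4, 3, X)
            cf = starvation_closed_forms(10, 0.2, 4, 3, 1, 1, 0, 0, X)
            assert s1 == pytest.approx(cf["equilibrium"][0], rel=1e-12)
            assert s2 == pytest.approx(cf["equilibrium"][1], rel=1e-12)

    def test_f_identical_to_starvation(self):
        ze = experience(10, 0.2, 4, 3)
        zs = starvation(10, 0.2, 4, 3)
        for X in np.logspace(-2, 2, 10):
            assert ze.closed_f(X, 1.0) == pytest.approx(zs.closed_f(X, 1.0), rel=1e-12)


class TestPanic:
    def test_all_ones_hand_equilibrium(self):
        cf = panic_closed_forms(1, 1, 1, 1, 1.0, 1.0)
        assert cf["E"] == pytest.approx(SQRT2 - 1, rel=1e-12)
        assert cf["P"] == pytest.approx(2 - SQRT2, rel=1e-12)
        assert cf["S"] == pytest.approx(1 / SQRT2, rel=1e-12)
        assert cf["H"] == pytest.approx(1 - 1 / SQRT2, rel=1e-12)
        assert cf["f"] == pytest.approx(1 - 1 / SQRT2, rel=1e-12)

    def test_f_equals_capture_flux(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b, c, d = rng.uniform(0.2, 5.0, 4)
            X, Y = rng.uniform(0.1, 10.0, 2)
            cf = panic_closed_forms(a, b, c, d, X, Y)
            assert cf["f"] == pytest.approx(c * cf["E"] * cf["S"] / Y, rel=1e-10)
            assert cf["pred_birth_prop"] == pytest.approx(cf["f"] / d, rel=1e-12)

    def test_conservation_over_random_parameters(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a, b, c, d = rng.uniform(0.1, 10.0, 4)
            X, Y = rng.uniform(0.0, 10.0, 2)
            if X == 0 and Y == 0:
                continue
            cf = panic_closed_forms(a, b, c, d, X, Y)
            assert cf["E"] + cf["P"] == pytest.approx(X, abs=1e-12 * (1 + X))
            assert cf["S"] + cf["H"] == pytest.approx(Y, abs=1e-12 * (1 + Y))

    def test_holling2_limit_p_to_zero(self):
        a, c, d = 1e-8, 10.0, 1.0  # p = a/b -> 0
        for X in (0.2, 1.0, 5.0):
            for Y in (0.5, 2.0):
                cf = panic_closed_forms(a, 1.0, c, d, X, Y)
                limit = c * X / (1.0 + c * X / d)
                assert cf["f"] == pytest.approx(limit, rel=1e-4)

    def test_prey_available_limit_q_to_inf(self):
        b, c = 0.2, 1e-8  # q = d/c -> inf
        p = 1.0 / b
        for X in (0.2, 1.0, 5.0):
            for Y in (0.5, 2.0):
                cf = panic_closed_forms(1.0, b, c, 1.0, X, Y)
                limit = c * X * Y / (p + Y)
                assert cf["f"] == pytest.approx(limit, rel=1e-4)

    def test_numerical_responses(self):
        cf = panic_closed_forms(1, 1, 1, 1, 1.0, 1.0, delta1=0.2, delta2=0.6,
                                mu1=0.3, mu2=0.1)
        f = cf["f"]
        assert cf["pred_death"] == pytest.approx(0.2 * (1 - f) + 0.6 * f, rel=1e-12)
        assert cf["prey_birth_prop"] == pytest.approx(cf["P"], rel=1e-12)  # X = 1
        assert cf["prey_death"] == pytest.approx(0.3 * cf["E"] + 0.1 * cf["P"], rel=1e-12)

    def test_rejects_double_zero_totals(self):
        with pytest.raises(ValueError):
            panic_closed_forms(1, 1, 1, 1, 0.0, 0.0)


class TestHollingBDMappings:
    def test_m1_tiered_is_holling2(self):
        zm = tiered_prey(1, [], [], [3.0], 2.0)
        canon = holling_bd_mappings("holling2", {"c1": 3.0, "d": 2.0})
        assert canon.coefficients == {"a": 3.0, "b": 1.5}
        for X in np.logspace(-2, 2, 10):
            assert canon.evaluate(X) == pytest.approx(zm.closed_f(X, 1.0), rel=1e-12)

    def test_bd_mapping_matches_c2_zero_two_state(self):
        A12, A1, c1, d = 2.0, 0.5, 10.0, 1.0
        canon = holling_bd_mappings(
            "beddington_deangelis", {"A12": A12, "A1": A1, "c1": c1, "d": d}
        )
        assert canon.coefficients == pytest.approx(
            {"a": c1, "b": c1 / d, "c": A1 / A12}
        )
        assert canon.as_printed["a"] == pytest.approx(c1 * A12)
        for X in np.logspace(-1, 1, 5):
            for Y in (0.5, 2.0):
                _, _, f2 = two_state_prey_closed_forms(A12, A1, c1, 0.0, d, X, Y)
                assert canon.evaluate(X, Y) == pytest.approx(f2, rel=1e-12)

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            holling_bd_mappings("holling1", {})


class TestAlleeSignature:
    def test_predator_growth_superlinear_at_low_Y(self):
        # with c1 = 0 predators eat only flushed-out prey, so the
        # population birth rate gamma*f*Y vanishes faster than Y
        zm = two_state_prey(2.0, 0.5, 1e-12, 15.0, 1.0)
        X = 0.1
        Ys = [0.4, 0.2, 0.1, 0.05]
        growth = []
        for Y in Ys:
            eq = solve_nonlinear(zm.model, X, Y, allow_relaxed=True)
            birth = float(zm.rates.pred_birth @ eq.y_hat)  # gamma*f*Y
            growth.append(birth)
        for g_prev, g_half in zip(growth, growth[1:]):
            assert g_half < 0.51 * g_prev


def test_zoo_builder_registry_complete():
    assert set(ZOO_BUILDERS) == {
        "tiered", "two_state_prey", "dd_handling", "starvation",
        "experience", "panic",
    }
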