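"""Manifold geometry: coordinates, Fisher metric, distances."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import patsep as ps
from patsep.manifold import base_plus, q11_bounds


def random_interior_law(rng, margin=1e-3):
    """Rejection-sample a joint law with all outcomes above ``margin``."""
    while True:
        q = rng.dirichlet(np.ones(4))
        if q.min() > margin:
            return ps.JointLaw(*q)


class TestTheta:
    def test_uniform_independent_law_is_zero(self):
        assert ps.theta_of(ps.JointLaw(0.25, 0.25, 0.25, 0.25)) == 0.0

    def test_hand_evaluated_log_odds(self):
        # log(0.4*0.4 / (0.1*0.1)) = log 16
        q = ps.JointLaw(0.4, 0.1, 0.1, 0.4)
        assert ps.theta_of(q) == pytest.approx(math.log(16), abs=1e-12)

    def test_factorized_law_is_zero(self, rng):
        for _ in range(20):
            e1, e2 = rng.uniform(0.05, 0.95, 2)
            q = ps.JointLaw(
                (1 - e1) * (1 - e2), e1 * (1 - e2), (1 - e1) * e2, e1 * e2
            )
            assert ps.theta_of(q) == pytest.approx(0.0, abs=1e-12)

    def test_vanishing_q11_signals_negative_divergence(self):
        with pytest.raises(ps.ThetaUndefinedError) as err:
            ps.theta_of(ps.JointLaw(0.5, 0.25, 0.25, 0.0))
        assert err.value.sign == -1

    def test_vanishing_q10_signals_positive_divergence(self):
        with pytest.raises(ps.ThetaUndefinedError) as err:
            ps.theta_of(ps.JointLaw(0.5, 0.0, 0.25, 0.25))
        assert err.value.sign == +1

    def test_monotone_in_q11_at_fixed_marginals(self):
        eta1, eta2 = 0.4, 0.5
        lo, hi = q11_bounds(eta1, eta2)
        grid = np.linspace(lo + 1e-3, hi - 1e-3, 50)
        thetas = [
            ps.theta_of(
                ps.JointLaw(1 - eta1 - eta2 + q, eta1 - q, eta2 - q, q)
            )
            for q in grid
        ]
        assert np.all(np.diff(thetas) > 0)


class TestEtas:
    @pytest.mark.parametrize(
        "q, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), (0.5, 0.5)),
            ((0.72, 0.10, 0.16, 0.02), (0.12, 0.18)),
            ((1.0, 0.0, 0.0, 0.0), (0.0, 0.0)),
        ],
    )
    def test_marginals_are_outcome_sums(self, q, expected):
        assert ps.etas_of(ps.JointLaw(*q)) == pytest.approx(expected)


class TestLawOf:
    def test_independence_gives_product_q11(self):
        law = ps.law_of(ps.Coordinates(0.5, 0.1, 0.0))
        assert law.q11 == pytest.approx(0.05, abs=1e-14)

    def test_strong_correlation_limit_against_bisection(self):
        c = ps.Coordinates(0.5, 0.5, 20.0)
        law = ps.law_of(c)
        # independent oracle: bisection on the monotone map q11 -> theta
        lo, hi = 1e-15, 0.5 - 1e-15
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            t = math.log(
                mid * (mid) / ((0.5 - mid) * (0.5 - mid))
            )  # q00 = q11 here since eta1 + eta2 = 1
            if t < 20.0:
                lo = mid
            else:
                hi = mid
        assert law.q11 == pytest.approx(0.5 * (lo + hi), abs=1e-9)
        assert law.q11 == pytest.approx(0.5, abs=1e-3)
        assert law.q10 == pytest.approx(0.0, abs=1e-3)

    def test_round_trip_on_random_interior_laws(self, rng):
        for _ in range(1000):
            q = random_interior_law(rng)
            eta1, eta2 = ps.etas_of(q)
            c = ps.Coordinates(eta1, eta2, ps.theta_of(q))
            back = ps.law_of(c)
            assert np.allclose(
                back.as_array(), q.as_array(), atol=1e-10, rtol=0
            )

    def test_coordinate_round_trip(self, rng):
        for _ in range(200):
            q = random_interior_law(rng)
            c = ps.Coordinates(*ps.etas_of(q), ps.theta_of(q))
            law = ps.law_of(c)
            assert ps.theta_of(law) == pytest.approx(c.theta, abs=1e-10)
            assert ps.etas_of(law) == pytest.approx(
                (c.eta1, c.eta2), abs=1e-10
            )


class TestLogProb:
    def test_silent_outcome_is_log_q00(self):
        c = ps.Coordinates(0.3, 0.6, 0.4)
        q = ps.law_of(c)
        assert ps.log_prob((0, 0), c) == pytest.approx(math.log(q.q00))

    def test_independent_coactivation(self):
        assert ps.log_prob((1, 1), ps.Coordinates(0.5, 0.5, 0.0)) == (
            pytest.approx(math.log(0.25))
        )

    def test_expansion_matches_lookup_and_normalizes(self, rng):
        for _ in range(20):
            q = random_interior_law(rng)
            c = ps.Coordinates(*ps.etas_of(q), ps.theta_of(q))
            # log-linear expansion evaluated directly
            a1 = math.log(q.q10 / q.q00)
            a2 = math.log(q.q01 / q.q00)
            th = ps.theta_of(q)
            total = 0.0
            for x1 in (0, 1):
                for x2 in (0, 1):
                    lp = ps.log_prob((x1, x2), c)
                    expansion = (
                        a1 * x1 + a2 * x2 + th * x1 * x2 + math.log(q.q00)
                    )
                    assert lp == pytest.approx(expansion, abs=1e-10)
                    total += math.exp(lp)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestFisher:
    def test_independent_point_closed_form(self):
        g = ps.fisher_information(ps.Coordinates(0.5, 0.5, 0.0)).matrix
        assert g[0, 0] == pytest.approx(4.0, rel=1e-6)
        assert g[1, 1] == pytest.approx(4.0, rel=1e-6)
        assert abs(g[0, 1]) < 1e-6

    def test_closed_form_any_independent_marginals(self):
        # at theta = 0 the marginal block is diagonal with 1/(eta(1-eta))
        for e1, e2 in [(0.3, 0.6), (0.1, 0.8)]:
            g = ps.fisher_information(ps.Coordinates(e1, e2, 0.0)).matrix
            assert g[0, 0] == pytest.approx(1 / (e1 * (1 - e1)), rel=1e-5)
            assert g[1, 1] == pytest.approx(1 / (e2 * (1 - e2)), rel=1e-5)
            assert abs(g[0, 1]) < 1e-6

    def test_brute_force_expectation_oracle(self):
        # independent oracle: score by symmetric differences on log q
        # directly from the quadratic-free construction at theta = 0
        e1, e2, step = 0.4, 0.25, 1e-6

        def log_probs(a, b):
            return np.log(
                [(1 - a) * (1 - b), a * (1 - b), (1 - a) * b, a * b]
            )

        s1 = (log_probs(e1 + step, e2) - log_probs(e1 - step, e2)) / (2 * step)
        s2 = (log_probs(e1, e2 + step) - log_probs(e1, e2 - step)) / (2 * step)
        q = np.exp(log_probs(e1, e2))
        g = ps.fisher_information(ps.Coordinates(e1, e2, 0.0)).matrix
        assert g[0, 0] == pytest.approx(float((s1 * s1 * q).sum()), rel=1e-5)
        assert g[1, 1] == pytest.approx(float((s2 * s2 * q).sum()), rel=1e-5)
        assert g[0, 1] == pytest.approx(float((s1 * s2 * q).sum()), abs=1e-6)

    def test_orthogonality_on_grid(self):
        worst = 0.0
        for e1 in np.linspace(0.15, 0.85, 10):
            for e2 in np.linspace(0.15, 0.85, 10):
                for th in np.linspace(-2.0, 2.0, 10):
                    g = ps.fisher_information(
                        ps.Coordinates(e1, e2, th)
                    ).matrix
                    worst = max(worst, abs(g[0, 2]), abs(g[1, 2]))
        assert worst < 1e-6

    def test_positive_semidefinite_on_random_grid(self, rng):
        for _ in range(25):
            q = random_interior_law(rng, margin=5e-3)
            c = ps.Coordinates(*ps.etas_of(q), ps.theta_of(q))
            g = ps.fisher_information(c).matrix
            assert np.linalg.eigvalsh(g).min() >= -1e-9

    def test_symmetric_law_gives_equal_marginal_entries(self):
        # q10 = q01 implies eta1 = eta2, hence g(eta1,eta1) = g(eta2,eta2)
        q = ps.JointLaw(0.35, 0.2, 0.2, 0.25)
        c = ps.Coordinates(*ps.etas_of(q), ps.theta_of(q))
        g = ps.fisher_information(c).matrix
        assert g[0, 0] == pytest.approx(g[1, 1], rel=1e-6)

    def test_boundary_rejected(self):
        with pytest.raises(ps.InfeasibleCoordinatesError):
            ps.fisher_information(ps.Coordinates(0.5, 0.5, 22.0))


class TestSquaredDistance:
    def test_zero_step_is_zero(self):
        c = ps.Coordinates(0.4, 0.3, 0.2)
        assert ps.squared_distance(c, ps.TangentStep()) == 0.0

    def test_theta_only_step_uses_g_theta_theta(self):
        c = ps.Coordinates(0.4, 0.3, 0.2)
        g = ps.fisher_information(c).matrix
        d = ps.TangentStep(d_theta=0.05)
        assert ps.squared_distance(c, d) == pytest.approx(
            g[2, 2] * 0.05**2, abs=1e-10
        )

    def test_marginal_only_step_uses_marginal_block(self):
        c = ps.Coordinates(0.4, 0.3, 0.2)
        g = ps.fisher_information(c).matrix
        d = ps.TangentStep(d_eta1=0.01, d_eta2=-0.02)
        expect = (
            g[0, 0] * 0.01**2
            + g[1, 1] * 0.02**2
            + 2 * g[0, 1] * 0.01 * -0.02
        )
        assert ps.squared_distance(c, d) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize(
        "direction",
        [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0), (0.6, -0.4, 0.8)],
    )
    def test_matches_twice_kl_to_first_order(self, direction):
        c = ps.Coordinates(0.4, 0.3, 0.5)
        ratios = []
        for eps in (1e-2, 1e-3):
            d = ps.TangentStep(*(eps * v for v in direction))
            ds2 = ps.squared_distance(c, d)
            kl = ps.kl_divergence(ps.law_of(c), ps.law_of(base_plus(c, d)))
            ratios.append(ds2 / (2 * kl))
        assert ratios[1] == pytest.approx(1.0, abs=1e-2)
        # first-order convergence: the deviation shrinks with epsilon
        assert abs(ratios[1] - 1) < abs(ratios[0] - 1)

    def test_infeasible_step_rejected(self):
        c = ps.Coordinates(0.9, 0.3, 0.0)
        with pytest.raises(ps.InfeasibleCoordinatesError):
            ps.squared_distance(c, ps.TangentStep(d_eta1=0.2))


class TestSerialization:
    def test_joint_law_json_round_trip(self):
        q = ps.JointLaw(0.4, 0.1, 0.1, 0.4)
        assert ps.JointLaw.from_json(q.to_json()) == q

    def test_coordinates_json_round_trip(self):
        c = ps.Coordinates(0.3, 0.6, -1.2)
        assert ps.Coordinates.from_json(c.to_json()) == c


@given(
    st.floats(0.05, 0.95),
    st.floats(0.05, 0.95),
    st.floats(-3.0, 3.0),
)
def test_law_of_always_feasible_and_invertible(e1, e2, th):
    c = ps.Coordinates(e1, e2, th)
    law = ps.law_of(c)
    qs = law.as_array()
    assert qs.min() >= 0 and abs(qs.sum() - 1) < 1e-12
    if law.is_interior(1e-9):
        assert ps.theta_of(law) == pytest.approx(th, abs=1e-8)
        assert ps.etas_of(law) == pytest.approx((e1, e2), abs=1e-10)
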