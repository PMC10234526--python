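"""Zero-cumulant moment closure: exactness on linear networks and closure algebra."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from shadownoise import (ClosureError, NonConvergenceError, build_network,
                         close_third_moment, closed_form_moments,
                         derive_moment_odes, make_fixture, stationary_moments)
from shadownoise.model_core import (Reaction, ReactionNetwork, Species,
                                    SystemConfig)
from shadownoise.moments import closed_moment_poly, solve_stationary


class TestClosureIdentity:
    def test_zero_means_give_zero_third_moment(self):
        M = np.array([[2.0, 0.3], [0.3, 1.0]])
        m = np.zeros(2)
        for ijk in itertools.product(range(2), repeat=3):
            assert close_third_moment(m, M, ijk) == 0.0

    def test_diagonal_case_reduces_to_univariate_gaussian_identity(self):
        mu, m2 = 1.7, 4.1
        out = close_third_moment(np.array([mu]), np.array([[m2]]), (0, 0, 0))
        assert out == pytest.approx(3 * mu * m2 - 2 * mu ** 3)

    def test_independent_species_factorize(self):
        m = np.array([1.0, 2.0, 3.0])
        M = np.outer(m, m) + np.diag([0.5, 0.7, 0.9])  # cov = 0 off-diagonal
        out = close_third_moment(m, M, (0, 1, 2))
        assert out == pytest.approx(m[0] * m[1] * m[2])

    @given(st.tuples(st.integers(0, 2), st.integers(0, 2), st.integers(0, 2)))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_under_index_permutation(self, ijk):
        rng = np.random.default_rng(0)
        m = rng.normal(size=3)
        A = rng.normal(size=(3, 3))
        M = A @ A.T + np.outer(m, m)
        vals = {close_third_moment(m, M, p) for p in itertools.permutations(ijk)}
        assert max(vals) - min(vals) < 1e-9

    def test_generic_expansion_matches_explicit_gaussian_formula(self):
        rng = np.random.default_rng(1)
        m = rng.uniform(1, 3, size=3)
        A = rng.normal(size=(3, 3))
        M = A @ A.T + np.outer(m, m)
        y = {}  # state lookup: moment key -> value
        for i in range(3):
            y[(i,)] = m[i]
        for i in range(3):
            for j in range(i, 3):
                y[(i, j)] = M[i, j]
        for idx in [(0, 1, 2), (0, 0, 1), (2, 2, 2)]:
            poly = closed_moment_poly(idx, 2)
            val = sum(c * np.prod([y[k] for k in keys]) for c, keys in poly)
            assert val == pytest.approx(close_third_moment(m, M, idx))


def two_species_linear_network():
    """X -> X + Y cascade: linear, with nontrivial cov(X, Y)."""
    return ReactionNetwork(
        species=[Species(name="X", role="free_tf"), Species(name="Y", role="mrna")],
        reactions=[
            Reaction("bx", (), (("X", 1),), 4.0, "constant", ()),
            Reaction("dx", (("X", 1),), (), 1.0, "first", ("X",)),
            Reaction("tx", (("X", 1),), (("X", 1), ("Y", 1)), 3.0, "first", ("X",)),
            Reaction("dy", (("Y", 1),), (), 2.0, "first", ("Y",)),
        ],
        conservation_groups=[], initial_state={})


class TestMomentOdes:
    def test_birth_death_first_moment_equation(self):
        net = make_fixture("birth_death", k=10, alpha=2)
        system = derive_moment_odes(net, order=2)
        # dE[R]/dt at E[R]=0: k; at E[R]=5: k - alpha*5 = 0
        y = np.zeros(system.n)
        assert system.rhs(y)[system.key_index[(0,)]] == pytest.approx(10.0)
        y[system.key_index[(0,)]] = 5.0
        y[system.key_index[(0, 0)]] = 30.0  # E[R^2] = var + mean^2
        rhs = system.rhs(y)
        assert rhs[system.key_index[(0,)]] == pytest.approx(0.0)

    def test_burst_fluctuation_term_scales_with_square_of_burst_size(self):
        net = make_fixture("bursty_birth_death", beta=0.33, n=4, delta=2.7)
        system = derive_moment_odes(net, order=2)
        # at the zero state d E[T^2]/dt = n^2 * beta
        rhs = system.rhs(np.zeros(system.n))
        assert rhs[system.key_index[(0, 0)]] == pytest.approx(16 * 0.33)

    def test_closure_is_vacuous_for_first_order_networks(self):
        net = two_species_linear_network()
        s2 = derive_moment_odes(net, order=2)
        s3 = derive_moment_odes(net, order=3)
        st2 = solve_stationary(s2)
        st3 = solve_stationary(s3)
        np.testing.assert_allclose(st2.mean, st3.mean, rtol=1e-7)
        np.testing.assert_allclose(st2.cov, st3.cov, rtol=1e-6, atol=1e-9)

    def test_higher_order_propensities_are_rejected(self):
        net = two_species_linear_network()
        bad = Reaction("bad", (("X", 1),), (("Y", 1),), 1.0, "first", ("X",))
        object.__setattr__(bad, "order", "third")
        net.reactions.append(bad)
        with pytest.raises(ClosureError):
            derive_moment_odes(net, order=2)


class TestStationarySolve:
    def test_birth_death_matches_poisson_law(self):
        st = stationary_moments(make_fixture("birth_death", k=10, alpha=2))
        assert st.mean_of("R") == pytest.approx(5.0, rel=1e-6)
        assert st.var_of("R") == pytest.approx(5.0, rel=1e-6)

    def test_bursty_fixture_matches_closed_form(self):
        st = stationary_moments(make_fixture("bursty_birth_death"))
        cf = closed_form_moments("bursty_birth_death")
        assert st.mean_of("T1") == pytest.approx(cf.mean_of("T1"), rel=1e-6)
        assert st.var_of("T1") == pytest.approx(cf.var_of("T1"), rel=1e-6)

    def test_telegraph_promoter_matches_closed_form_including_covariance(self):
        st = stationary_moments(make_fixture("telegraph"))
        cf = closed_form_moments("telegraph")
        assert st.mean_of("R") == pytest.approx(cf.mean_of("R"), rel=1e-6)
        assert st.var_of("R") == pytest.approx(cf.var_of("R"), rel=1e-6)
        assert st.cov_of("G1", "R") == pytest.approx(cf.cov_of("G1", "R"), rel=1e-6)

    def test_enhancer_state_means_are_a_probability_distribution(self, kruppel_network):
        st = stationary_moments(kruppel_network)
        assert st.mean_of("A0") + st.mean_of("A1") == pytest.approx(1.0, abs=1e-8)
        assert st.mean_of("B0") + st.mean_of("B1") == pytest.approx(1.0, abs=1e-8)
        assert st.converged and not st.pathological

    def test_species_relabeling_permutes_state_consistently(self, kruppel_network):
        st = stationary_moments(kruppel_network)
        order = tuple(reversed(st.species))
        perm = st.permuted(order)
        assert perm.mean_of("R") == st.mean_of("R")
        assert perm.cov_of("T1", "R") == st.cov_of("T1", "R")

    def test_nonconvergence_carries_last_state(self):
        net = make_fixture("birth_death", k=10, alpha=2)
        system = derive_moment_odes(net)
        with pytest.raises(NonConvergenceError) as err:
            solve_stationary(system, tol=1e-30, t_max=10.0)
        assert err.value.state.converged is False
        assert err.value.state.mean_of("R") > 0

    def test_order3_preserves_grid_trends_qualitatively(self):
        # noise falls with added T1 sites under both truncation orders
        cvs = {}
        for order in (2, 3):
            vals = []
            for tau1 in (1, 2, 3):
                net = build_network(SystemConfig(enhancers=((tau1, 0),)))
                state = stationary_moments(net, order=order)
                vals.append(np.sqrt(state.var_of("R")) / state.mean_of("R"))
            cvs[order] = vals
        for order, vals in cvs.items():
            assert vals[0] > vals[1] > vals[2], order
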