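"""Scheme construction, rate matrices, discretization, and stationary analysis."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cftrhmm as ch
from cftrhmm.kinetics import (
    ReducibleChainError,
    SchemeError,
    StateDistribution,
    TransitionMatrix,
    RateMatrix,
    embedded_jump_chain,
    dump_scheme,
    load_scheme,
)
from helpers import power_iteration_stationary, taylor_expm

EXPECTED_EDGES = {
    ("C1a", "C1b"), ("C1b", "C1a"), ("C1b", "C2"), ("C2", "C1b"),
    ("C2", "O1"), ("O1", "C2"), ("O1", "O2"), ("O2", "C3"),
    ("C3", "O2"), ("C3", "C4"), ("C4", "C3"), ("C4", "C1a"),
}


class TestDefaultScheme:
    def test_states_and_conductance(self, scheme):
        assert scheme.state_names == ("C1a", "C1b", "C2", "O1", "O2", "C3", "C4")
        assert scheme.conductance_map["O1"] == 1
        assert scheme.conductance_map["O2"] == 1
        for s in ("C1a", "C1b", "C2", "C3", "C4"):
            assert scheme.conductance_map[s] == 0

    def test_topology_is_the_twelve_edge_cycle(self, scheme):
        assert scheme.edges == frozenset(EXPECTED_EDGES)
        # hydrolysis and ADP release are irreversible
        assert ("O2", "O1") not in scheme.edges
        assert ("C1a", "C4") not in scheme.edges

    def test_single_atp_dependent_edge(self, scheme):
        assert scheme.atp_dependent_edges == frozenset({("C1a", "C1b")})

    @pytest.mark.parametrize(
        "edge,rate",
        [
            (("C1a", "C1b"), 9.0e3),
            (("C1b", "C1a"), 5.0),
            (("C1b", "C2"), 7.7),
            (("C2", "C1b"), 5.8),
            (("C2", "O1"), 4.9),
            (("O1", "C2"), 10.0),
            (("O1", "O2"), 7.1),
            (("O2", "C3"), 3.0),
            (("C3", "O2"), 7.0),
            (("C3", "C4"), 6.0),
            (("C4", "C3"), 12.8),
            (("C4", "C1a"), 1.7),
        ],
    )
    def test_rate_constants(self, scheme, edge, rate):
        assert scheme.rate_params[edge] == rate

    def test_all_rates_positive(self, scheme):
        assert all(r > 0 for r in scheme.rate_params.values())

    def test_invalid_schemes_rejected(self):
        with pytest.raises(SchemeError):
            ch.KineticScheme(("A", "A"), {"A": 0}, {})
        with pytest.raises(SchemeError):
            ch.KineticScheme(("A", "B"), {"A": 0, "B": 2}, {})
        with pytest.raises(SchemeError):
            ch.KineticScheme(("A", "B"), {"A": 0, "B": 1}, {("A", "B"): -1.0})


class TestRateMatrix:
    def test_atp_scaling_of_binding_edge(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        assert R.values[scheme.index("C1a"), scheme.index("C1b")] == pytest.approx(9.0)

    def test_missing_edges_are_zero(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        assert R.values[scheme.index("O2"), scheme.index("O1")] == 0.0
        assert R.values[scheme.index("C1a"), scheme.index("C4")] == 0.0

    @pytest.mark.parametrize("atp", [5e-5, 1e-3, 5e-3])
    def test_rows_sum_to_zero(self, scheme, atp):
        R = ch.rate_matrix(scheme, atp)
        assert np.abs(R.values.sum(axis=1)).max() < 1e-10

    def test_nonpositive_atp_rejected(self, scheme):
        for atp in (0.0, -1e-3):
            with pytest.raises(ValueError):
                ch.rate_matrix(scheme, atp)


class TestDiscretize:
    def test_zero_generator_gives_identity(self):
        R = RateMatrix(np.zeros((3, 3)), atp_concentration=1e-3, states=("a", "b", "c"))
        Q = ch.discretize(R, 0.01)
        assert np.allclose(Q.values, np.eye(3), atol=1e-14)

    def test_two_state_closed_form_and_series_oracle(self):
        a, b, dt = 1.0, 2.0, 0.5
        R = RateMatrix(
            np.array([[-a, a], [b, -b]]), atp_concentration=1e-3, states=("x", "y")
        )
        Q = ch.discretize(R, dt)
        # closed-form two-state exponential
        lam = a + b
        decay = np.exp(-lam * dt)
        expected = np.array(
            [
                [(b + a * decay) / lam, a * (1 - decay) / lam],
                [b * (1 - decay) / lam, (a + b * decay) / lam],
            ]
        )
        assert np.allclose(Q.values, expected, atol=1e-12)
        assert np.allclose(Q.values, taylor_expm(R.values * dt), atol=1e-10)

    def test_default_scheme_rows_sum_to_one(self, scheme):
        Q = ch.discretize(ch.rate_matrix(scheme, 0.5e-3), 0.01)
        assert np.abs(Q.values.sum(axis=1) - 1).max() < 1e-12

    def test_matches_series_oracle_on_default_scheme(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        Q = ch.discretize(R, 0.01)
        assert np.allclose(Q.values, taylor_expm(R.values * 0.01), atol=1e-10)

    def test_nonpositive_dt_rejected(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        for dt in (0.0, -0.01):
            with pytest.raises(ValueError):
                ch.discretize(R, dt)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        dt1=st.floats(min_value=1e-4, max_value=0.5),
        dt2=st.floats(min_value=1e-4, max_value=0.5),
    )
    def test_semigroup_property(self, dt1, dt2):
        scheme = ch.build_cftr_scheme()
        R = ch.rate_matrix(scheme, 1e-3)
        lhs = ch.discretize(R, dt1 + dt2).values
        rhs = ch.discretize(R, dt1).values @ ch.discretize(R, dt2).values
        assert np.abs(lhs - rhs).max() < 1e-10

    @pytest.mark.parametrize("dt", [1e-4, 1e-5])
    def test_short_time_expansion(self, scheme, dt):
        R = ch.rate_matrix(scheme, 1e-3)
        Q = ch.discretize(R, dt)
        err = np.abs(Q.values - (np.eye(7) + R.values * dt)).max()
        assert err <= 200.0 * dt**2

    def test_off_topology_entries_small_but_nonzero(self, scheme, Q_1mM):
        mask = scheme.adjacency() | np.eye(7, dtype=bool)
        off = Q_1mM.values[~mask]
        assert np.all(off > 0)  # multi-step paths within one sample
        assert off.max() < 5e-3


class TestStationary:
    def test_single_state_identity(self):
        Q = TransitionMatrix(np.eye(1), dt=0.01, states=("only",))
        assert ch.stationary_distribution(Q).probs == pytest.approx([1.0])

    def test_symmetric_two_state(self):
        Q = TransitionMatrix(
            np.array([[0.7, 0.3], [0.3, 0.7]]), dt=0.01, states=("a", "b")
        )
        assert np.allclose(ch.stationary_distribution(Q).probs, [0.5, 0.5], atol=1e-12)

    def test_default_scheme_matches_power_iteration(self, Q_1mM):
        pi = ch.stationary_distribution(Q_1mM).probs
        assert np.abs(pi - power_iteration_stationary(Q_1mM.values)).max() < 1e-8

    def test_reducible_chain_reports_classes(self):
        Q = TransitionMatrix(np.eye(2), dt=0.01, states=("a", "b"))
        with pytest.raises(ReducibleChainError, match="communicating classes"):
            ch.stationary_distribution(Q)


class TestEvolve:
    def test_zero_time_is_identity(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        P0 = StateDistribution.point_mass("C1a", scheme.state_names)
        assert np.allclose(ch.evolve(P0, R, 0.0).probs, P0.probs, atol=1e-14)

    def test_probability_conserved(self, scheme):
        R = ch.rate_matrix(scheme, 1e-3)
        P0 = StateDistribution.point_mass("O2", scheme.state_names)
        out = ch.evolve(P0, R, 3.7)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_is_fixed_point(self, scheme, Q_1mM, pi_1mM):
        R = ch.rate_matrix(scheme, 1e-3)
        out = ch.evolve(pi_1mM, R, 5.0)
        assert np.abs(out.probs - pi_1mM.probs).max() < 1e-10

    def test_negative_time_rejected(self, scheme, pi_1mM):
        with pytest.raises(ValueError):
            ch.evolve(pi_1mM, ch.rate_matrix(scheme, 1e-3), -1.0)


class TestJumpChain:
    def test_supported_exactly_on_edges(self, scheme):
        P = embedded_jump_chain(ch.rate_matrix(scheme, 1e-3))
        mask = scheme.adjacency()
        assert np.all(P.values[~mask] == 0)
        assert np.all(P.values[mask] > 0)
        assert np.abs(P.values.sum(axis=1) - 1).max() < 1e-12


class TestSchemeFile:
    def test_round_trip(self, scheme, tmp_path):
        path = tmp_path / "wt.scheme"
        dump_scheme(scheme, path)
        loaded = load_scheme(path)
        assert loaded.state_names == scheme.state_names
        assert loaded.conductance_map == dict(scheme.conductance_map)
        assert loaded.rate_params == dict(scheme.rate_params)
        assert loaded.atp_dependent_edges == scheme.atp_dependent_edges

    def test_malformed_line_names_location(self, tmp_path):
        path = tmp_path / "bad.scheme"
        path.write_text("state A 0\nstate B 1\nedge A B not_a_number\n")
        with pytest.raises(SchemeError, match="bad.scheme:3"):
            load_scheme(path)

    def test_unknown_directive_rejected(self, tmp_path):
        path = tmp_path / "bad.scheme"
        path.write_text("vertex A 0\n")
        with pytest.raises(SchemeError, match="unknown directive"):
            load_scheme(path)
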