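"""Rate-matrix construction, equilibria and spectral decomposition."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

from fretkin.kinetics import (
    KineticNetwork,
    build_rate_matrix,
    eigen_decompose,
    equilibrium_constant,
    equilibrium_fractions,
    mean_efficiency,
)


def random_detailed_balance_network(rng, n=3):
    """Random irreducible network satisfying detailed balance."""
    x = rng.dirichlet(np.ones(n) * 2.0)
    A = rng.uniform(0.5, 5.0, size=(n, n))
    A = (A + A.T) / 2.0  # symmetric fluxes
    rates = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                rates[(j, i)] = A[i, j] / x[j]  # K[i,j] x_j = A sym
    return build_rate_matrix(n, rates), x


class TestBuildRateMatrix:
    def test_symmetric_two_state(self):
        net = build_rate_matrix(2, {(0, 1): 5.0, (1, 0): 5.0})
        assert np.allclose(net.K, [[-5, 5], [5, -5]])

    def test_three_state_chain_matrix(self):
        # MF <-> LF <-> HF with all rates 5, LF the middle state
        net = build_rate_matrix(
            3,
            {("MF", "LF"): 5, ("LF", "MF"): 5, ("LF", "HF"): 5, ("HF", "LF"): 5},
            state_labels=("MF", "LF", "HF"),
        )
        assert np.allclose(net.K, [[-5, 5, 0], [5, -10, 5], [0, 5, -5]])

    def test_no_rates_gives_zero_matrix(self):
        net = build_rate_matrix(3, {})
        assert np.allclose(net.K, 0.0)
        assert np.allclose(np.linalg.eigvals(net.K), 0.0)

    @pytest.mark.parametrize("bad", [
        {(0, 1): -1.0},        # negative rate
        {(1, 1): 2.0},         # self transition
        {(0, 5): 1.0},         # index out of range
    ])
    def test_validation_errors(self, bad):
        with pytest.raises(ValueError):
            build_rate_matrix(3, bad)

    @given(st.integers(2, 5), st.randoms(use_true_random=False))
    @settings(max_examples=25, deadline=None)
    def test_column_sums_zero(self, n, pyrandom):
        rates = {}
        for i in range(n):
            for j in range(n):
                if i != j and pyrandom.random() < 0.7:
                    rates[(j, i)] = pyrandom.uniform(0.0, 10.0)
        net = build_rate_matrix(n, rates)
        assert np.abs(net.K.sum(axis=0)).max() < 1e-12


class TestEquilibrium:
    def test_two_state_3_1(self):
        # k12 = 3 (2 -> 1), k21 = 1 (1 -> 2): x_d = (0.75, 0.25)
        net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
        assert np.allclose(equilibrium_fractions(net), [0.75, 0.25])

    def test_symmetric_chain_uniform(self):
        net = build_rate_matrix(
            3, {(0, 1): 5, (1, 0): 5, (1, 2): 5, (2, 1): 5})
        assert np.allclose(equilibrium_fractions(net), 1 / 3)

    def test_matches_gillespie_occupancy(self):
        """Long-run CTMC occupancy equals the stationary solution."""
        rng = np.random.default_rng(7)
        net, _ = random_detailed_balance_network(rng)
        x = equilibrium_fractions(net)
        # independent Gillespie oracle, >= 1e6 jumps
        esc = -np.diag(net.K)
        t_tot = np.zeros(net.n_states)
        s = 0
        waits = rng.exponential(1.0, size=2_000_000)
        us = rng.random(2_000_000)
        branch = []
        for j in range(net.n_states):
            p = net.K[:, j].copy()
            p[j] = 0
            branch.append(np.cumsum(p / p.sum()))
        for k in range(1_000_000):
            dt = waits[k] / esc[s]
            t_tot[s] += dt
            s = int(np.searchsorted(branch[s], us[k]))
        occ = t_tot / t_tot.sum()
        assert np.abs(occ - x).max() < 0.01

    def test_reducible_network_names_groups(self):
        net = build_rate_matrix(
            4, {(0, 1): 1, (1, 0): 1, (2, 3): 1, (3, 2): 1},
            state_labels=("A", "B", "C", "D"))
        with pytest.raises(ValueError, match="reducible"):
            equilibrium_fractions(net)


class TestEigenDecompose:
    def test_two_state_100us_relaxation(self):
        net = build_rate_matrix(2, {(0, 1): 5.0, (1, 0): 5.0})
        es = eigen_decompose(net)
        assert np.allclose(es.eigenvalues, [0.0, -10.0])
        assert np.allclose(es.relaxation_times, [0.1])  # 100 us

    def test_linear_chain_67_and_200us(self):
        net = build_rate_matrix(
            3, {(0, 1): 5, (1, 0): 5, (1, 2): 5, (2, 1): 5})
        es = eigen_decompose(net)
        assert np.allclose(np.sort(es.eigenvalues), [-15, -5, 0])
        assert np.allclose(np.sort(es.relaxation_times * 1e3), [200 / 3, 200])

    def test_spectral_reconstruction_vs_expm(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            net, _ = random_detailed_balance_network(rng)
            es = eigen_decompose(net)
            for t in (0.05, 0.2, 1.0):
                ref = scipy.linalg.expm(net.K * t)
                assert np.abs(es.propagator(t) - ref).max() < 1e-10

    def test_projector_algebra(self):
        rng = np.random.default_rng(3)
        net, _ = random_detailed_balance_network(rng)
        es = eigen_decompose(net)
        n = net.n_states
        assert np.allclose(es.projectors.sum(axis=0), np.eye(n), atol=1e-9)
        for l in range(n):
            for m in range(n):
                prod = es.projectors[l] @ es.projectors[m]
                ref = es.projectors[l] if l == m else np.zeros((n, n))
                assert np.abs(prod - ref).max() < 1e-8

    def test_propagator_columns_are_probabilities(self):
        rng = np.random.default_rng(13)
        net, _ = random_detailed_balance_network(rng)
        es = eigen_decompose(net)
        for t in (0.01, 0.1, 1.0, 10.0):
            P = es.propagator(t)
            assert np.all(P > -1e-10)
            assert np.allclose(P.sum(axis=0), 1.0, atol=1e-9)

    def test_n_minus_one_relaxations(self):
        rng = np.random.default_rng(17)
        for n in (2, 3, 4):
            net, _ = random_detailed_balance_network(rng, n)
            es = eigen_decompose(net)
            assert len(es.relaxation_times) == n - 1
            assert np.all(es.eigenvalues[1:] < 0)


class TestObservables:
    def test_mean_efficiency_values(self):
        assert mean_efficiency([0.75, 0.25], [0.8, 0.2]) == pytest.approx(0.65)
        assert mean_efficiency([1.0, 0.0], [0.8, 0.2]) == pytest.approx(0.8)
        assert mean_efficiency([2 / 3, 1 / 3], [0.8, 0.2]) == pytest.approx(0.6)

    def test_mean_efficiency_errors(self):
        with pytest.raises(ValueError):
            mean_efficiency([0.5, 0.5], [0.8])
        with pytest.raises(ValueError):
            mean_efficiency([0.5, 0.6], [0.8, 0.2])

    def test_equilibrium_constant(self):
        net = build_rate_matrix(2, {(1, 0): 3.0, (0, 1): 1.0})
        assert equilibrium_constant(net) == pytest.approx(1 / 3)
        sym = build_rate_matrix(2, {(1, 0): 2.0, (0, 1): 2.0})
        assert equilibrium_constant(sym) == pytest.approx(1.0)
        # consistency with the stationary fractions
        x = equilibrium_fractions(net)
        assert equilibrium_constant(net) == pytest.approx(x[1] / x[0], abs=1e-12)

    def test_equilibrium_constant_requires_two_states(self):
        net = build_rate_matrix(3, {(0, 1): 1, (1, 0): 1, (1, 2): 1, (2, 1): 1})
        with pytest.raises(ValueError):
            equilibrium_constant(net)


def test_network_config_roundtrip(tmp_path):
    from fretkin.io import load_network, save_network

    net = build_rate_matrix(
        3, {("LF", "MF"): 5, ("MF", "LF"): 2.5, ("MF", "HF"): 1.2,
            ("HF", "MF"): 0.7},
        state_labels=("LF", "MF", "HF"))
    path = tmp_path / "net.yaml"
    save_network(path, net)
    back = load_network(path)
    assert back.state_labels == net.state_labels
    assert np.allclose(back.K, net.K)


def test_invalid_network_rejected():
    with pytest.raises(ValueError):
        KineticNetwork(K=np.array([[1.0, 0.0], [0.0, -1.0]]))  # bad columns
    with pytest.raises(ValueError):
        KineticNetwork(K=np.array([[-1.0, -2.0], [1.0, 2.0]]))  # negative off-diag
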