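"""Pool gradients, hardware biasing and adaptive ansatz growth."""

import networkx as nx
import numpy as np
import pytest

from csvqe.adapt import (BiasConfig, adapt_run, bias_factor, pauli_pool,
                         pool_gradient)
from csvqe.circuits import circuit_graph, CircuitIR, line_graph, ring_graph
from csvqe.paulis import PauliSum, PauliTerm, random_pauli_sum


def test_gradient_zero_for_commuting_operator():
    H = PauliSum.from_strings({"ZZ": 1.0})
    psi = np.zeros(4, dtype=complex)
    psi[0] = 1.0
    assert pool_gradient(H, psi, PauliTerm.from_string("ZI")) == 0.0


def test_gradient_textbook_value():
    # H = Z, P = Y, |psi> = |+>: i[Z, Y] = 2X and <+|2X|+> = 2
    H = PauliSum.from_strings({"Z": 1.0})
    psi = np.array([1.0, 1.0], dtype=complex) / np.sqrt(2)
    assert pool_gradient(H, psi, PauliTerm.from_string("Y")) == \
        pytest.approx(2.0)


@pytest.mark.parametrize("seed", range(4))
def test_gradient_matches_finite_difference(seed):
    from csvqe.circuits import compile_exponential

    rng = np.random.default_rng(seed)
    n = 4
    H = random_pauli_sum(n, 20, seed=seed)
    x, z = int(rng.integers(1, 16)), int(rng.integers(0, 16))
    P = PauliTerm(1.0, x, z, n)
    psi = rng.standard_normal(16) + 1j * rng.standard_normal(16)
    psi /= np.linalg.norm(psi)
    g = pool_gradient(H, psi, P)
    h = 1e-5
    M = H.to_dense_matrix()

    def energy(th):
        import scipy.linalg as sla
        U = sla.expm(1j * th * P.to_sum().to_dense_matrix())
        v = U @ psi
        return np.real(np.vdot(v, M @ v))

    fd = (energy(h) - energy(-h)) / (2 * h)
    assert abs(g - fd) < 1e-6


def test_bias_factor_embedding_and_zero_cases():
    cfg = BiasConfig(max_depth=2, strength=1.0)
    gc = line_graph(3)
    assert bias_factor(gc, line_graph(5), cfg) == 1.0      # d = 0
    # a triangle can never embed in a tree, and deleting up to D=0 nodes
    # cannot help
    tri = nx.cycle_graph(3)
    nx.set_edge_attributes(tri, 1.0, "weight")
    assert bias_factor(tri, line_graph(6), BiasConfig(0, 1.0)) == 0.0


def test_bias_factor_arithmetic():
    # s(n)/W = 0.25 with b = 2 gives 0.5625
    gc = nx.Graph()
    gc.add_edge(0, 1, weight=1.0)
    gc.add_edge(1, 2, weight=1.0)
    gc.add_edge(2, 3, weight=1.0)
    gc.add_edge(3, 4, weight=1.0)
    # deleting leaf node 0 removes weight 1 of W=4
    target = line_graph(4)
    val = bias_factor(gc, target, BiasConfig(max_depth=1, strength=2.0))
    assert val == pytest.approx((1 - 0.25) ** 2)


def test_bias_factor_nonincreasing_in_strength():
    gc = nx.Graph()
    for e in ((0, 1), (1, 2), (2, 3), (3, 4)):
        gc.add_edge(*e, weight=1.0)
    vals = [bias_factor(gc, line_graph(4), BiasConfig(1, b))
            for b in (0.5, 1.0, 2.0, 4.0)]
    assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


def test_adapt_single_qubit_converges_from_plus_state():
    H = PauliSum.from_strings({"Z": 1.0})
    pool = [PauliTerm.from_string("Y")]
    plus = np.array([1.0, 1.0], dtype=complex) / np.sqrt(2)
    res = adapt_run(H, pool, initial_state=plus, max_cycles=3)
    assert res.energy == pytest.approx(-1.0, abs=1e-6)


def test_adapt_handles_zero_gradient_start():
    # from |0> every pool gradient vanishes by symmetry: must terminate
    H = PauliSum.from_strings({"Z": 1.0})
    pool = [PauliTerm.from_string("Y")]
    res = adapt_run(H, pool, initial_state=0, max_cycles=3)
    assert res.energy == pytest.approx(-1.0, abs=1e-3) or \
        res.energy == pytest.approx(1.0, abs=1e-6)


def test_energy_trace_nonincreasing():
    H = random_pauli_sum(3, 14, seed=2)
    K = random_pauli_sum(3, 6, seed=5, hermitian=False)
    K = PauliSum(K.x, K.z, 1j * np.abs(K.coeffs), 3)
    pool = pauli_pool(K)
    res = adapt_run(H, pool, max_cycles=6)
    assert all(a >= b - 1e-9 for a, b in
               zip(res.energy_trace, res.energy_trace[1:]))


def test_pool_from_generator_dedupes_and_orders():
    K = PauliSum.from_strings([("XY", 0.5j), ("YX", 0.5j), ("XY", 0.25j),
                               ("II", 1.0)])
    pool = pauli_pool(K)
    strings = [p.pauli_string() for p in pool]
    assert "II" not in strings
    assert sorted(set(strings)) == sorted(strings)


def test_hardware_aware_run_prefers_embeddable_operators():
    """With a line target, the biased run never selects an operator whose
    circuit fails to embed while embeddable scored operators exist."""
    H = random_pauli_sum(4, 18, seed=7)
    K = random_pauli_sum(4, 8, seed=8, hermitian=False)
    K = PauliSum(K.x, K.z, 1j * np.abs(K.coeffs), 4)
    pool = pauli_pool(K)
    target = line_graph(4)
    cfg = BiasConfig(max_depth=1, strength=1.0)
    res = adapt_run(H, pool, target_graph=target, cfg=cfg, max_cycles=3)
    # every appended block keeps the ansatz within one deleted node of the
    # target topology
    g = circuit_graph(res.circuit)
    if g.number_of_edges():
        assert bias_factor(g, target, cfg) > 0.0
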