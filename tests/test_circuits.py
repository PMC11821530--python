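"""Circuit IR, Pauli-exponential compilation and routing."""

import numpy as np
import pytest
import scipy.linalg as sla

from csvqe.circuits import (CircuitIR, circuit_graph, compile_exponential,
                            heavy_hex_falcon, line_graph, read_edge_list,
                            ring_graph, ring_subgraph, route_and_count,
                            write_edge_list)
from csvqe.paulis import PauliTerm

from conftest import dense_pauli


def test_exponential_single_z_is_one_rz():
    c = compile_exponential(PauliTerm.from_string("Z"), 0.4)
    assert [g.name for g in c.gates] == ["Rz"]
    ref = sla.expm(1j * 0.4 * dense_pauli("Z"))
    assert np.allclose(c.unitary(), ref, atol=1e-12)


def test_exponential_xx_structure_and_unitary():
    c = compile_exponential(PauliTerm.from_string("XX"), 0.9)
    names = [g.name for g in c.gates]
    assert names.count("CNOT") == 2 and names.count("Rz") == 1
    ref = sla.expm(1j * 0.9 * dense_pauli("XX"))
    assert np.allclose(c.unitary(), ref, atol=1e-10)


def test_exponential_zero_angle_is_identity():
    c = compile_exponential(PauliTerm.from_string("XYZ"), 0.0)
    assert np.allclose(c.unitary(), np.eye(8), atol=1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_exponential_matches_expm_random(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 5))
    while True:
        x, z = int(rng.integers(0, 1 << n)), int(rng.integers(0, 1 << n))
        if x | z:
            break
    P = PauliTerm(1.0, x, z, n)
    th = float(rng.uniform(-2, 2))
    ref = sla.expm(1j * th * dense_pauli(P.pauli_string()))
    assert np.allclose(compile_exponential(P, th).unitary(), ref, atol=1e-10)


def test_parameterised_exponential_binds_late():
    P = PauliTerm.from_string("XY")
    c = compile_exponential(P, "t")
    assert c.parameters() == ["t"]
    ref = sla.expm(1j * 0.7 * dense_pauli("XY"))
    assert np.allclose(c.unitary({"t": 0.7}), ref, atol=1e-10)


def test_circuit_graph_counts_two_qubit_gates():
    c = CircuitIR(4)
    c.add("CNOT", (0, 1))
    c.add("CNOT", (1, 2)).add("CNOT", (2, 3)).add("CNOT", (1, 2))
    G = circuit_graph(c)
    assert G[0][1]["weight"] == 1 and G[1][2]["weight"] == 2
    total = sum(d["weight"] for _, _, d in G.edges(data=True))
    assert total == c.two_qubit_count()


def test_ring_subgraph_in_heavy_hex_and_absent_in_tree():
    dev = heavy_hex_falcon()
    ring = ring_subgraph(12, dev)
    assert ring is not None and len(ring) == 12
    for i in range(12):
        assert dev.has_edge(ring[i], ring[(i + 1) % 12])
    assert ring_subgraph(3, line_graph(6)) is None


def test_routing_conformance_and_equivalence():
    c = CircuitIR(4)
    c.add("H", 0).add("CNOT", (0, 3)).add("Rz", 2, 0.3).add("CNOT", (1, 2))
    dev = line_graph(4)
    routed, layout, ncx = route_and_count(c, dev)
    for g in routed.gates:
        if len(g.qubits) == 2:
            assert dev.has_edge(*g.qubits)
    # CNOT(0,3) on a path needs SWAPs: 3 per inserted SWAP
    assert ncx >= c.cnot_count()
    # statevector equivalence up to the final qubit relabeling
    v1 = c.statevector()
    t2 = routed.statevector().reshape((2,) * 4)
    t2 = np.moveaxis(t2, [layout[l] for l in range(4)], range(4))
    assert abs(abs(np.vdot(t2.reshape(-1), v1)) - 1.0) < 1e-10


def test_routing_conformant_circuit_unchanged():
    c = CircuitIR(3)
    c.add("CNOT", (0, 1)).add("CNOT", (1, 2))
    routed, layout, ncx = route_and_count(c, line_graph(3))
    assert ncx == 2
    assert layout == {0: 0, 1: 1, 2: 2}


def test_inverse_cancellation():
    c = CircuitIR(2)
    c.add("CNOT", (0, 1)).add("CNOT", (0, 1)).add("H", 0).add("H", 0)
    routed, _, ncx = route_and_count(c, line_graph(2))
    assert ncx == 0 and len(routed.gates) == 0


def test_edge_list_roundtrip(tmp_path):
    G = ring_graph(6)
    p = tmp_path / "dev.txt"
    write_edge_list(p, G)
    G2 = read_edge_list(p)
    assert {frozenset(e) for e in G2.edges()} == \
        {frozenset(e) for e in G.edges()}


def test_qasm_export_mentions_all_gates():
    c = CircuitIR(2)
    c.add("H", 0).add("CNOT", (0, 1)).add("Rz", 1, 0.25)
    qasm = c.to_qasm()
    assert "OPENQASM 2.0" in qasm and "cx q[0],q[1];" in qasm \
        and "rz(0.25) q[1];" in qasm
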