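"""QWC grouping, shot estimation, readout mitigation and ZNE."""

import numpy as np
import pytest

from csvqe.circuits import (CircuitIR, heavy_hex_falcon, heavy_hex_lattice,
                            line_graph)
from csvqe.measurement import (NoiseModel, ZNEConfig, apply_confusion,
                               estimate_energy, gain_factor, mem_apply,
                               qwc_partition, simulate_counts,
                               tile_assignments, zne_amplify,
                               zne_extrapolate, zne_energy)
from csvqe.paulis import PauliSum, qubit_wise_commutes, random_pauli_sum


def _fixture_circuit():
    c = CircuitIR(2)
    c.add("Ry", 0, 0.9).add("CNOT", (0, 1)).add("Ry", 1, -0.4)
    return c


def test_all_z_hamiltonian_is_one_group():
    H = PauliSum.from_strings({"ZI": 1.0, "IZ": 0.5, "ZZ": 0.25})
    gp = qwc_partition(H)
    assert len(gp.groups) == 1
    assert gp.groups[0][0] == "ZZ"


def test_three_term_example_needs_two_groups():
    # {ZI, IZ, XX}: brute-force minimal colouring of the 3-node graph is 2
    H = PauliSum.from_strings({"ZI": 1.0, "IZ": 1.0, "XX": 1.0})
    gp = qwc_partition(H)
    assert len(gp.groups) == 2


def test_partition_is_valid_and_complete():
    H = random_pauli_sum(4, 25, seed=3)
    gp = qwc_partition(H)
    members = []
    for basis, grp in gp.groups:
        ts = grp.terms()
        members.extend(ts)
        for i in range(len(ts)):
            for j in range(i + 1, len(ts)):
                assert qubit_wise_commutes(ts[i], ts[j])
    n_identity = sum(1 for t in H.terms() if t.is_identity)
    assert len(members) == H.n_terms - n_identity


def test_noiseless_estimator_unbiased():
    H = random_pauli_sum(3, 12, seed=4)
    c = CircuitIR(3)
    c.add("H", 0).add("CNOT", (0, 1)).add("Ry", 2, 0.7)
    exact = H.expectation(c.statevector())
    e, s = estimate_energy(H, c, shots=400000, seed=2)
    assert s > 0
    assert abs(e - exact) < 4 * s + 1e-9


def test_identity_hamiltonian_has_zero_stderr():
    H = PauliSum.identity(2, 1.25)
    e, s = estimate_energy(H, _fixture_circuit(), shots=100, seed=0)
    assert e == pytest.approx(1.25) and s == 0.0


def test_variance_scales_inversely_with_shots():
    H = PauliSum.from_strings({"ZI": 0.7, "XX": 0.4})
    c = _fixture_circuit()
    exact = H.expectation(c.statevector())

    def spread(shots, n_rep=30):
        es = [estimate_energy(H, c, shots=shots, seed=k)[0]
              for k in range(n_rep)]
        return np.var(es)

    v1, v2 = spread(200), spread(3200)
    assert v2 < v1 / 4   # expect ~1/16; allow generous slack


def test_mem_inverts_confusion_channel():
    noise = NoiseModel.uniform(3, 0, 0, p01=0.08, p10=0.15)
    rng = np.random.default_rng(0)
    p = rng.dirichlet(np.ones(8))
    rec = mem_apply(apply_confusion(p, noise, 3), noise)
    assert np.abs(rec - p).max() < 1e-10


def test_mem_recovers_pure_state_distribution():
    # single qubit prepared in |0>, confusion A = [[.9,.1],[.2,.8]]
    noise = NoiseModel(readout={0: np.array([[0.9, 0.1], [0.2, 0.8]])})
    noisy = apply_confusion(np.array([1.0, 0.0]), noise, 1)
    assert np.allclose(noisy, [0.9, 0.1])
    rec = mem_apply(noisy, noise)
    assert np.allclose(rec, [1.0, 0.0], atol=1e-10)


def test_mem_rejects_singular_confusion():
    noise = NoiseModel(readout={0: np.array([[0.5, 0.5], [0.5, 0.5]])})
    with pytest.raises(np.linalg.LinAlgError):
        mem_apply(np.array([0.6, 0.4]), noise)


def test_joint_confusion_is_tensor_product():
    noise = NoiseModel.uniform(2, 0, 0, p01=0.1, p10=0.2)
    A0 = noise.confusion_matrix(0)
    A1 = noise.confusion_matrix(1)
    e00 = np.zeros(4)
    e00[0] = 1.0
    joint = apply_confusion(e00, noise, 2)
    assert joint[3] == pytest.approx(A0[0, 1] * A1[0, 1])


@pytest.mark.parametrize("lam", [1, 2, 3])
def test_zne_amplification_preserves_unitary(lam):
    c = CircuitIR(3)
    c.add("H", 0).add("CNOT", (0, 1)).add("Ry", 2, 0.4).add("CNOT", (2, 0))
    U0, U = c.unitary(), zne_amplify(c, lam).unitary()
    k = int(np.argmax(np.abs(U0)))
    phase = U.flat[k] / U0.flat[k]
    assert np.allclose(U, phase * U0, atol=1e-10)


@pytest.mark.parametrize("lam", [1, 2, 3])
def test_zne_gate_counts(lam):
    c = CircuitIR(2)
    c.add("CNOT", (0, 1))
    amp = zne_amplify(c, lam)
    assert amp.cnot_count() == 2 * lam
    n_1q = sum(1 for g in amp.gates if len(g.qubits) == 1)
    assert n_1q == 3 * lam + 2


def test_gain_factor_properties():
    c = CircuitIR(3)
    c.add("H", 0).add("CNOT", (0, 1)).add("CNOT", (1, 2))
    pure2q = NoiseModel.uniform(3, 0.0, 5e-3)
    assert gain_factor(c, 1, pure2q) == pytest.approx(1.0)
    assert gain_factor(c, 3, pure2q) == pytest.approx(3.0)
    mixed = NoiseModel.uniform(3, 1e-3, 5e-3)
    g2, g3 = gain_factor(c, 2, mixed), gain_factor(c, 3, mixed)
    assert 1.0 < g2 < 2.0 and g2 < g3 < 3.0


def test_extrapolation_closed_form():
    # all-equal data extrapolates to itself
    e0, v0, _ = zne_extrapolate([(1, -2.0, 1.0), (2, -2.0, 1.0),
                                 (3, -2.0, 1.0)], order=1)
    assert e0 == pytest.approx(-2.0)
    # exact linear data with equal weights: OLS intercept
    e0, v0, _ = zne_extrapolate([(1, -1.0, 1.0), (2, -0.9, 1.0),
                                 (3, -0.8, 1.0)], order=1)
    assert e0 == pytest.approx(-1.1)
    with pytest.raises(ValueError):
        zne_extrapolate([(1, -1.0, 1.0)], order=1)


def test_zne_recovers_noiseless_energy_within_2_sigma():
    H = PauliSum.from_strings({"ZI": 0.6, "IZ": 0.3, "XX": 0.5})
    c = _fixture_circuit()
    exact = H.expectation(c.statevector())
    noise = NoiseModel.uniform(2, 1e-4, 8e-3, p01=0.01, p10=0.02)
    res = zne_energy(H, c, None, noise, ZNEConfig((1, 2, 3), 1, 20000),
                     seed=5)
    raw, _ = estimate_energy(H, c, noise=noise, shots=20000, seed=11)
    assert abs(res.extrapolated - exact) < abs(raw - exact) + 2e-3
    assert np.all(np.diff(res.gains) > 0)


def test_mitigation_beats_raw_in_most_trials():
    """MEM + ZNE jointly reduce the error in >= 90% of seeded trials."""
    H = PauliSum.from_strings({"ZI": 0.6, "IZ": 0.3, "XX": 0.5,
                               "YY": -0.2})
    c = _fixture_circuit()
    exact = H.expectation(c.statevector())
    noise = NoiseModel.uniform(2, 1e-4, 5e-3, p01=0.03, p10=0.05)
    wins = 0
    n_trials = 50
    for k in range(n_trials):
        raw, _ = estimate_energy(H, c, noise=noise, shots=4000,
                                 seed=1000 + k, mem=False)
        res = zne_energy(H, c, None, noise, ZNEConfig((1, 2, 3), 1, 4000),
                         seed=1000 + k, mem=True)
        if abs(res.extrapolated - exact) < abs(raw - exact):
            wins += 1
    assert wins >= int(0.9 * n_trials)


def test_tiling_counts_on_reference_devices():
    import networkx as nx

    assert len(tile_assignments(line_graph(5), heavy_hex_falcon())) == 5
    g16 = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 5), (1, 4), (4, 7), (5, 8),
                    (6, 7), (7, 10), (8, 9), (8, 11), (10, 12), (12, 13),
                    (13, 14), (11, 14), (12, 15)])
    assert len(tile_assignments(line_graph(5), g16)) == 3
    tiles = tile_assignments(line_graph(5), heavy_hex_lattice(3, 6))
    assert len(tiles) >= 24
    used = [q for t in tiles for q in t]
    assert len(used) == len(set(used))     # disjoint


def test_tile_averaging_reduces_variance():
    H = PauliSum.from_strings({"ZI": 0.6, "XX": 0.5})
    c = _fixture_circuit()

    def estimate(n_tiles, seed):
        es = [estimate_energy(H, c, shots=400, seed=seed * 97 + j)[0]
              for j in range(n_tiles)]
        return float(np.mean(es))

    v1 = np.var([estimate(1, k) for k in range(40)])
    v5 = np.var([estimate(5, k) for k in range(40)])
    assert v5 < v1 / 2
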