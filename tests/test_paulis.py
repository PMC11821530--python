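"""Symplectic Pauli algebra against dense matrix oracles."""

import itertools

import numpy as np
import pytest
import scipy.linalg as sla
from hypothesis import given, settings, strategies as hst

from csvqe.paulis import (PauliSum, PauliTerm, commutes, is_noncontextual,
                          qubit_wise_commutes, random_pauli_sum,
                          read_pauli_file, write_pauli_file)

from conftest import dense_pauli, dense_sum


@pytest.mark.parametrize("n", [1, 2])
def test_multiply_matches_kronecker_product_exhaustively(n):
    for a in itertools.product("IXYZ", repeat=n):
        for b in itertools.product("IXYZ", repeat=n):
            sa, sb = "".join(a), "".join(b)
            prod = PauliTerm.from_string(sa) * PauliTerm.from_string(sb)
            ref = dense_pauli(sa) @ dense_pauli(sb)
            got = prod.coefficient * dense_pauli(prod.pauli_string())
            assert np.allclose(ref, got), (sa, sb)


def test_multiply_identity_and_phase_examples():
    X = PauliTerm.from_string("X")
    assert (X * X).is_identity and (X * X).coefficient == 1.0
    ZY = PauliTerm.from_string("Z") * PauliTerm.from_string("Y")
    assert ZY.pauli_string() == "X" and np.isclose(ZY.coefficient, -1j)
    t = PauliTerm.from_string("XZ") * PauliTerm.from_string("ZZ")
    # phase from qubit 0 only: (X Z) (x) (Z Z) = (-iY) (x) I
    assert t.pauli_string() == "YI" and np.isclose(t.coefficient, -1j)


def test_multiply_rejects_mismatched_lengths():
    with pytest.raises(ValueError):
        PauliTerm.from_string("X") * PauliTerm.from_string("XX")


def test_commutes_matches_dense_commutator():
    rng = np.random.default_rng(0)
    for _ in range(120):
        sa = "".join(rng.choice(list("IXYZ"), 3))
        sb = "".join(rng.choice(list("IXYZ"), 3))
        A, B = dense_pauli(sa), dense_pauli(sb)
        want = np.allclose(A @ B, B @ A)
        assert commutes(PauliTerm.from_string(sa),
                        PauliTerm.from_string(sb)) == want


def test_commutes_examples():
    assert not commutes(PauliTerm.from_string("X"), PauliTerm.from_string("Z"))
    assert commutes(PauliTerm.from_string("XX"), PauliTerm.from_string("ZZ"))
    ident = PauliTerm.from_string("II")
    for s in ("XY", "ZZ", "YI"):
        assert commutes(PauliTerm.from_string(s), ident)


def test_qubit_wise_commutation_implies_commutation():
    for a in itertools.product("IXYZ", repeat=2):
        for b in itertools.product("IXYZ", repeat=2):
            ta = PauliTerm.from_string("".join(a))
            tb = PauliTerm.from_string("".join(b))
            if qubit_wise_commutes(ta, tb):
                assert commutes(ta, tb)
    assert qubit_wise_commutes(PauliTerm.from_string("ZI"),
                               PauliTerm.from_string("IZ"))
    assert not qubit_wise_commutes(PauliTerm.from_string("XX"),
                                   PauliTerm.from_string("ZZ"))


def _brute_noncontextual(S):
    """Transitivity of commutation on the non-symmetry elements."""
    T = S.terms()
    m = len(T)
    comm = [[commutes(T[i], T[j]) for j in range(m)] for i in range(m)]
    sym = {i for i in range(m) if all(comm[i])}
    rest = [i for i in range(m) if i not in sym]
    for a, b, c in itertools.permutations(rest, 3):
        if comm[a][b] and comm[b][c] and not comm[a][c]:
            return False
    return True


def test_noncontextuality_examples():
    assert is_noncontextual(PauliSum.from_strings(
        {"ZI": 1.0, "IZ": 1.0, "ZZ": 1.0}))
    assert is_noncontextual(PauliSum.from_strings(
        {"X": 1.0, "Y": 1.0, "Z": 1.0}))
    assert not is_noncontextual(PauliSum.from_strings(
        {"XI": 1.0, "ZI": 1.0, "XX": 1.0, "ZZ": 1.0}))


@settings(max_examples=80, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10 ** 6), m=hst.integers(2, 8))
def test_noncontextuality_matches_brute_force_transitivity(seed, m):
    S = random_pauli_sum(3, m, seed=seed)
    assert is_noncontextual(S) == _brute_noncontextual(S)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10 ** 6), scale=hst.floats(0.1, 10))
def test_noncontextuality_invariant_under_rescaling_and_reorder(seed, scale):
    S = random_pauli_sum(3, 6, seed=seed)
    ref = is_noncontextual(S)
    perm = np.random.default_rng(seed).permutation(S.n_terms)
    S2 = PauliSum(S.x[perm], S.z[perm], S.coeffs[perm] * scale, 3)
    assert is_noncontextual(S2) == ref


def test_l1_norm():
    assert PauliSum.zero(2).l1_norm() == 0.0
    assert PauliSum.from_strings({"X": 2.0, "Z": -3.0}).l1_norm() == 5.0
    H = random_pauli_sum(4, 25, seed=9)
    assert np.isclose(H.l1_norm(), np.abs(H.coeffs).sum())
    H2 = random_pauli_sum(4, 25, seed=10)
    assert (H + H2).l1_norm() <= H.l1_norm() + H2.l1_norm() + 1e-12


def test_ground_energy_examples_and_oracle():
    assert np.isclose(PauliSum.from_strings({"Z": 1.0}).ground_energy_exact(),
                      -1.0)
    assert np.isclose(
        PauliSum.from_strings({"X": 3.0, "Z": 4.0}).ground_energy_exact(),
        -5.0)
    H = random_pauli_sum(5, 40, seed=3)
    w = np.linalg.eigvalsh(dense_sum(H))
    assert np.isclose(H.ground_energy_exact(), w[0], atol=1e-8)


def test_matrix_and_statevector_agree_with_dense_oracle():
    H = random_pauli_sum(4, 30, seed=1)
    M = dense_sum(H)
    assert np.allclose(H.to_dense_matrix(), M)
    rng = np.random.default_rng(5)
    v = rng.standard_normal(16) + 1j * rng.standard_normal(16)
    assert np.allclose(H.apply_to_statevector(v), M @ v)
    op = H.to_linear_operator()
    assert np.allclose(op @ v, M @ v)


def test_random_pauli_sum_reproducible_and_hermitian():
    A = random_pauli_sum(4, 12, seed=42)
    B = random_pauli_sum(4, 12, seed=42)
    assert A.pauli_strings() == B.pauli_strings()
    assert np.allclose(A.coeffs, B.coeffs)
    assert A.n_terms <= 12
    M = A.to_dense_matrix()
    assert np.allclose(M, M.conj().T)


def test_rotation_matches_matrix_exponential():
    H = random_pauli_sum(3, 12, seed=5)
    P = PauliTerm.from_string("XZY")
    for theta in (0.3, np.pi / 2, -np.pi / 2):
        U = sla.expm(1j * theta / 2 * dense_pauli("XZY"))
        ref = U @ dense_sum(H) @ U.conj().T
        assert np.allclose(H.rotated(P, theta).to_dense_matrix(), ref,
                           atol=1e-10)


def test_canonicalization_merges_duplicates_and_drops_zeros():
    H = PauliSum.from_strings([("XZ", 1.0), ("XZ", -1.0), ("ZZ", 0.5),
                               ("ZZ", 0.25)])
    assert H.pauli_strings() == ["ZZ"]
    assert np.isclose(H.coeffs[0], 0.75)


def test_text_io_roundtrip(tmp_path):
    H = random_pauli_sum(5, 20, seed=3)
    path = tmp_path / "h.txt"
    write_pauli_file(path, H, comment="fixture")
    H2 = read_pauli_file(path)
    assert H2.n_qubits == H.n_qubits
    assert H2.pauli_strings() == H.pauli_strings()
    assert np.allclose(H2.coeffs, H.coeffs)
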