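import numpy as np
import pytest

from csvqe.chem.molecule import h2_geometry
from csvqe.chem.scf import run_rhf
from csvqe.pipeline import DiatomicStudy

_PAULI = {
    "I": np.eye(2, dtype=complex),
    "X": np.array([[0, 1], [1, 0]], dtype=complex),
    "Y": np.array([[0, -1j], [1j, 0]]),
    "Z": np.diag([1.0, -1.0]).astype(complex),
}


def dense_pauli(s: str) -> np.ndarray:
    """Kronecker-product oracle for a Pauli string (qubit 0 leftmost)."""
    m = np.array([[1.0]], dtype=complex)
    for ch in s:
        m = np.kron(m, _PAULI[ch])
    return m


def dense_sum(H) -> np.ndarray:
    """Dense oracle for a PauliSum built term by term via dense_pauli."""
    dim = 1 << H.n_qubits
    out = np.zeros((dim, dim), dtype=complex)
    for c, s in zip(H.coeffs, H.pauli_strings()):
        out += c * dense_pauli(s)
    return out


@pytest.fixture(scope="session")
def h2_scf():
    """RHF for H2 at the textbook separation 1.4 bohr."""
    return run_rhf(h2_geometry(1.4 * 0.529177210903))


@pytest.fixture(scope="session")
def study():
    """Shared N2/STO-3G study; caches SCF/FCI/subspace work across tests."""
    return DiatomicStudy(seed=7)


@pytest.fixture(scope="session")
def h2_study():
    return DiatomicStudy(geometry_factory=h2_geometry, seed=7)
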