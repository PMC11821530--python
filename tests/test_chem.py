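"""Electronic-structure engine: textbook anchors and internal cross-checks.

The strongest oracle is structural: the determinant-CI route and the
Jordan-Wigner qubit route share only the integrals, so agreement of their
ground energies validates both; H2 additionally pins the integrals to
published minimal-basis values, and CCSD must coincide with FCI for any
two-electron system.
"""

import numpy as np
import pytest

from csvqe.chem import (MolecularGeometry, build_qubit_hamiltonian, ccsd,
                        ccsd_t, excitation_generator, fci_ground,
                        hartree_fock_bitstring, mp2, mp2_natural_occupations,
                        n2_geometry, read_xyz, run_benchmarks, run_rhf,
                        write_xyz, h2_geometry)
from csvqe.chem.molecule import MolecularGeometry


def test_h2_matches_published_minimal_basis_values(h2_scf):
    # Restricted HF at 1.4 bohr in STO-3G (standard textbook case)
    assert abs(h2_scf.e_hf - (-1.1167)) < 2e-4
    assert abs(h2_scf.overlap[0, 1] - 0.6593) < 2e-4
    assert abs(h2_scf.eri[0, 0, 0, 0] - 0.7746) < 2e-4


def test_h2_fci_and_ccsd_coincide(h2_scf):
    e_fci = fci_ground(h2_scf.mo_hcore(), h2_scf.mo_eri(), 2, 1, 1,
                       h2_scf.e_nuc)
    assert abs(e_fci - (-1.137276)) < 2e-5
    cc = ccsd(h2_scf)
    # CCSD is exact for two electrons
    assert abs(h2_scf.e_hf + cc.e_corr - e_fci) < 1e-9


def test_qubit_hamiltonian_matches_determinant_fci(h2_scf):
    H = build_qubit_hamiltonian(h2_scf)
    assert H.n_qubits == 4 and H.is_hermitian()
    e_fci = fci_ground(h2_scf.mo_hcore(), h2_scf.mo_eri(), 2, 1, 1,
                       h2_scf.e_nuc)
    assert abs(H.ground_energy_exact() - e_fci) < 1e-8


def test_identity_coefficient_is_trace_over_dimension(h2_scf):
    H = build_qubit_hamiltonian(h2_scf)
    tr = np.trace(H.to_dense_matrix()).real
    assert abs(H.identity_coefficient().real - tr / 16) < 1e-10


def test_h2_mp2_generator_is_one_double_excitation(h2_scf):
    K = excitation_generator(h2_scf, "MP2")
    # a single spatial double excitation maps to 8 Pauli strings
    assert K.n_terms == 8
    assert np.allclose(K.coeffs.real, 0.0)          # anti-Hermitian
    # zero amplitudes give the empty generator
    cc = mp2(h2_scf)
    cc.t2 = np.zeros_like(cc.t2)
    K0 = excitation_generator(h2_scf, "MP2", cc_result=cc)
    assert K0.n_terms == 0


def test_n2_hamiltonian_is_20_qubits(study):
    b = study.bundle(1.1921)
    assert b.H_full.n_qubits == 20


def test_hamiltonian_invariant_under_rigid_motion():
    # translate + rotate H2; term count and l1 norm must be unchanged
    g0 = h2_geometry(0.9)
    scf0 = run_rhf(g0)
    H0 = build_qubit_hamiltonian(scf0)
    th = 0.7
    R = np.array([[1, 0, 0],
                  [0, np.cos(th), -np.sin(th)],
                  [0, np.sin(th), np.cos(th)]])
    coords = g0.coordinates @ R.T + np.array([0.3, -0.2, 0.5])
    g1 = MolecularGeometry(g0.atoms, coords)
    H1 = build_qubit_hamiltonian(run_rhf(g1))
    assert H0.n_terms == H1.n_terms
    assert abs(H0.l1_norm() - H1.l1_norm()) < 1e-8


def test_variational_methods_bounded_by_fci(study):
    r = 1.1921
    e_fci = study.fci(r)
    for m in ("HF", "CISD"):
        assert study.benchmark(r, m) >= e_fci - 1e-8
    e_cas = study.benchmark(r, "CASCI", active_space=(4, 2))
    assert e_fci - 1e-8 <= e_cas <= study.benchmark(r, "HF") + 1e-10


def test_ccsd_nonvariational_when_stretched(study):
    # coupled cluster dips below FCI at 2.0 A
    assert study.benchmark(2.0, "CCSD") < study.fci(2.0)


def test_run_benchmarks_rejects_unknown_and_casscf(study):
    geom = n2_geometry(1.2)
    with pytest.raises(ValueError):
        run_benchmarks(geom, ["FANCY"])
    with pytest.raises(ValueError):
        run_benchmarks(geom, ["CASSCF"])


def test_mp2_natural_occupations_physical(h2_scf):
    occ, U = mp2_natural_occupations(h2_scf)
    assert np.all(occ >= -1e-10) and np.all(occ <= 2 + 1e-10)
    assert abs(occ.sum() - 2.0) < 1e-8
    assert np.allclose(U @ U.T, np.eye(2), atol=1e-10)


def test_xyz_roundtrip(tmp_path):
    g = n2_geometry(1.25)
    p = tmp_path / "n2.xyz"
    write_xyz(p, g, comment="scan point")
    g2 = read_xyz(p)
    assert g2.atoms == g.atoms
    assert np.allclose(g2.coordinates, g.coordinates)
    assert g2.n_electrons == 14


def test_open_shell_reference_rejected():
    geom = MolecularGeometry(["N"], np.zeros((1, 3)), multiplicity=4)
    with pytest.raises(NotImplementedError):
        run_rhf(geom)
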