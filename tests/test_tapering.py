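"""Z2-symmetry identification and exact qubit removal."""

import numpy as np
import pytest

from csvqe.chem import build_qubit_hamiltonian, hartree_fock_bitstring
from csvqe.paulis import PauliSum, PauliTerm, random_pauli_sum
from csvqe.tapering import (StabilizerRotations, SymmetrySector,
                            find_symmetry_generators, select_sector, taper)


def test_single_qubit_z_hamiltonian():
    gens = find_symmetry_generators(PauliSum.from_strings({"Z": 1.0}))
    assert [g.pauli_string() for g in gens] == ["Z"]


def test_generators_commute_with_every_term(h2_scf):
    H = build_qubit_hamiltonian(h2_scf)
    gens = find_symmetry_generators(H)
    assert len(gens) == 3          # two spin parities + one point-group Z2
    for g in gens:
        assert H.commutes_with_term(g.x_mask, g.z_mask).all()


def test_h2_tapers_to_one_qubit_preserving_ground_energy(h2_scf):
    H = build_qubit_hamiltonian(h2_scf)
    gens = find_symmetry_generators(H)
    sector = select_sector(gens, hartree_fock_bitstring(h2_scf.n_occ, 4))
    Ht = taper(H, sector)
    assert Ht.n_qubits == 1
    assert abs(Ht.ground_energy_exact() - H.ground_energy_exact()) < 1e-8


def test_sector_eigenvalues_from_occupation():
    # Z on an occupied orbital gives -1 under |1> <-> occupied
    g = PauliTerm.from_string("ZIII")
    sec = select_sector([g], np.array([1, 1, 0, 0]))
    assert sec.eigenvalues == [-1]
    sec = select_sector([PauliTerm.from_string("IIZI")],
                        np.array([1, 1, 0, 0]))
    assert sec.eigenvalues == [1]
    with pytest.raises(ValueError):
        select_sector([PauliTerm.from_string("XIII")], np.array([1, 0, 0, 0]))


def test_empty_sector_returns_hamiltonian_unchanged():
    H = random_pauli_sum(3, 8, seed=2)
    out = taper(H, SymmetrySector([], []))
    assert out.pauli_strings() == H.pauli_strings()


def test_noncommuting_generator_rejected():
    H = PauliSum.from_strings({"XX": 1.0, "ZI": 0.5})
    g = PauliTerm.from_string("XI")   # commutes with XX but not ZI
    with pytest.raises(ValueError):
        taper(H, SymmetrySector([g], [1]))


def _planted_symmetry_hamiltonian(n, seed):
    """Random Hamiltonian commuting with a planted Z-type symmetry."""
    rng = np.random.default_rng(seed)
    sym = PauliTerm(1.0, 0, int(rng.integers(1, 1 << n)), n)
    H = random_pauli_sum(n, 40, seed=seed)
    keep = H.commutes_with_term(sym.x_mask, sym.z_mask)
    return PauliSum(H.x[keep], H.z[keep], H.coeffs[keep], n)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_isospectral_union_over_sectors(seed):
    """The union of tapered spectra over every sector equals the full
    spectrum as a set (multiplicities may change)."""
    H = _planted_symmetry_hamiltonian(5, seed)
    gens = find_symmetry_generators(H)
    assert gens
    full = np.linalg.eigvalsh(H.to_dense_matrix())
    collected = []
    k = len(gens)
    for bits in range(1 << k):
        eigs = [1 - 2 * ((bits >> j) & 1) for j in range(k)]
        Ht = taper(H, SymmetrySector(gens, eigs))
        collected.append(np.linalg.eigvalsh(Ht.to_dense_matrix()))
    collected = np.sort(np.concatenate(collected))
    # set equality of spectra up to numerical tolerance
    for e in np.unique(np.round(full, 8)):
        assert np.any(np.abs(collected - e) < 1e-7)
    for e in np.unique(np.round(collected, 8)):
        assert np.any(np.abs(full - e) < 1e-7)


def test_taper_never_increases_term_count(study):
    b = study.bundle(1.1921)
    assert b.Ht.n_terms <= b.H_full.n_terms
    assert b.Ht.n_qubits == b.H_full.n_qubits - 5


def test_sector_json_roundtrip():
    sec = SymmetrySector([PauliTerm.from_string("ZZII"),
                          PauliTerm.from_string("IIZZ")], [1, -1])
    sec2 = SymmetrySector.from_json(sec.to_json())
    assert [g.pauli_string() for g in sec2.generators] == ["ZZII", "IIZZ"]
    assert sec2.eigenvalues == [1, -1]


def test_batch_backmap_matches_scalar_backmap():
    H = _planted_symmetry_hamiltonian(5, 3)
    gens = find_symmetry_generators(H)
    rots = StabilizerRotations(gens, 5)
    n_red = 5 - len(rots.targets)
    rng = np.random.default_rng(0)
    xs = rng.integers(0, 1 << n_red, size=12).astype(np.uint64)
    zs = rng.integers(0, 1 << n_red, size=12).astype(np.uint64)
    xf, zf, c = rots.backmap_batch(xs, zs)
    for k in range(12):
        t = rots.backmap(PauliTerm(1.0, int(xs[k]), int(zs[k]), n_red))
        assert int(xf[k]) == t.x_mask and int(zf[k]) == t.z_mask
        assert np.isclose(c[k], t.coefficient)
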