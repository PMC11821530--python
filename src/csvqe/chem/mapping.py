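"""Jordan-Wigner mapping of the molecular Hamiltonian and cluster operators.

Spin-orbital convention: interleaved, qubit s = 2 p + sigma for spatial
orbital p and sigma in {alpha=0, beta=1}; occupation maps |1> <-> occupied.
The qubit Hamiltonian on 2M qubits is assembled from spin-summed orbital
excitation operators,

    H = E_nuc + sum_pq h'_pq E_pq + 1/2 sum_rs B_rs E_rs,
    B_rs = sum_pq (pq|rs) E_pq,   h'_ps = h_ps - 1/2 sum_r (pr|rs),

the same factorisation used by the determinant-CI module, which makes the
two routes (qubit diagonalization vs string CI) independent cross-checks
that share only the integrals.
"""

from __future__ import annotations

import numpy as np

from ..paulis import PauliSum
from .cc import ccsd, mp2
from .molecule import MolecularGeometry
from .scf import SCFResult, run_rhf

__all__ = ["jw_annihilation", "jw_creation", "build_qubit_hamiltonian",
           "excitation_generator", "hartree_fock_bitstring"]


def jw_annihilation(s: int, n_qubits: int) -> PauliSum:
    """a_s = Z_{<s} (X_s + i Y_s)/2 under |1> <-> occupied."""
    zmask = (1 << s) - 1
    xterm = (1 << s)
    return PauliSum(
        [xterm, xterm],
        [zmask, zmask | xterm],
        [0.5, 0.5j],
        n_qubits,
        canonicalize=False,
    )


def jw_creation(s: int, n_qubits: int) -> PauliSum:
    a = jw_annihilation(s, n_qubits)
    return PauliSum(a.x.copy(), a.z.copy(), np.conj(a.coeffs), a.n_qubits,
                    canonicalize=False)


def _concat(sums: list[PauliSum], n_qubits: int) -> PauliSum:
    if not sums:
        return PauliSum.zero(n_qubits)
    return PauliSum(
        np.concatenate([s.x for s in sums]),
        np.concatenate([s.z for s in sums]),
        np.concatenate([s.coeffs for s in sums]),
        n_qubits,
    )


def _spin_summed_excitations(M: int) -> list[PauliSum]:
    """E_pq = sum_sigma a^dag_{2p+sigma} a_{2q+sigma}, indexed p*M+q."""
    n = 2 * M
    ops = []
    for p in range(M):
        for q in range(M):
            parts = [jw_creation(2 * p + s, n) * jw_annihilation(2 * q + s, n)
                     for s in (0, 1)]
            ops.append(_concat(parts, n))
    return ops


def build_qubit_hamiltonian(source: MolecularGeometry | SCFResult,
                            tol: float = 1e-10) -> PauliSum:
    """Qubit Hamiltonian of the molecule on 2M qubits (Hartree units)."""
    scf = source if isinstance(source, SCFResult) else run_rhf(source)
    M = scf.n_orb
    h = scf.mo_hcore()
    g = scf.mo_eri()
    hp = h - 0.5 * np.einsum("prrs->ps", g)
    E = _spin_summed_excitations(M)
    parts = [PauliSum.identity(2 * M, scf.e_nuc)]
    for p in range(M):
        for q in range(M):
            c = hp[p, q]
            if abs(c) > tol:
                parts.append(E[p * M + q] * c)
    for r in range(M):
        for s in range(M):
            w = g[:, :, r, s]
            sub = [E[p * M + q] * w[p, q] for p in range(M) for q in range(M)
                   if abs(w[p, q]) > tol]
            if not sub:
                continue
            B = _concat(sub, 2 * M)
            parts.append((B * E[r * M + s]) * 0.5)
    H = _concat(parts, 2 * M)
    H.canonicalize(tol=1e-12)
    return H


def hartree_fock_bitstring(n_occ: int, n_qubits: int) -> np.ndarray:
    """Occupation bit per qubit for the restricted aufbau determinant."""
    occ = np.zeros(n_qubits, dtype=np.int64)
    occ[:2 * n_occ] = 1
    return occ


def excitation_generator(scf: SCFResult, source: str = "MP2",
                         include_singles: bool | None = None,
                         cc_result=None) -> PauliSum:
    """Anti-Hermitian JW image of the cluster excitation generator T - T^dag.

    ``source`` selects the amplitudes: MP2 (doubles only) or CCSD
    (singles + doubles by default).  Coefficients are purely imaginary in
    the Hermitian-term convention used by :class:`PauliSum`.
    """
    src = source.upper()
    if src == "MP2":
        cc = cc_result or mp2(scf)
        use_singles = False if include_singles is None else include_singles
    elif src == "CCSD":
        cc = cc_result or ccsd(scf)
        use_singles = True if include_singles is None else include_singles
    else:
        raise ValueError(f"unknown amplitude source {source!r}")
    no = 2 * scf.n_occ
    n = 2 * scf.n_orb
    parts = []

    def anti_hermitian(term: PauliSum, amp: float):
        dag = PauliSum(term.x.copy(), term.z.copy(), np.conj(term.coeffs),
                       n, canonicalize=False)
        parts.append(term * amp)
        parts.append(dag * (-amp))

    if use_singles and cc.t1 is not None:
        for i in range(no):
            for a_ in range(cc.t1.shape[1]):
                amp = cc.t1[i, a_]
                if abs(amp) < 1e-10:
                    continue
                a_q = no + a_
                anti_hermitian(jw_creation(a_q, n) * jw_annihilation(i, n),
                               amp)
    t2 = cc.t2
    nv = t2.shape[2]
    for i in range(no):
        for j in range(i + 1, no):
            for a_ in range(nv):
                for b_ in range(a_ + 1, nv):
                    amp = t2[i, j, a_, b_]
                    if abs(amp) < 1e-10:
                        continue
                    aq, bq = no + a_, no + b_
                    term = (jw_creation(aq, n) * jw_creation(bq, n)
                            * jw_annihilation(j, n) * jw_annihilation(i, n))
                    anti_hermitian(term, amp)
    K = _concat(parts, n)
    K.canonicalize(tol=1e-12)
    return K
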