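"""Restricted Hartree-Fock with damping, DIIS and scan continuation.

The reference throughout is spin-restricted; for the closed-shell singlets
treated here (H2, N2 scans) the restricted open-shell and restricted
formulations coincide, so a single RHF driver serves as the reference
determinant at every geometry.

Cold starts (core-Hamiltonian guess) are reliable near equilibrium but can
drop into high-lying stationary points at stretched diatomic geometries,
where several restricted configurations compete.  ``run_rhf`` therefore
continues the equilibrium solution outward in bond length for stretched
diatomics (warm-started DIIS along a short ladder), which keeps the whole
dissociation curve on the single smooth aufbau branch that standard
restricted references trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import build_basis
from .integrals import eri_tensor, one_electron_integrals
from .molecule import MolecularGeometry


class SCFConvergenceError(RuntimeError):
    """SCF failed to converge; carries iteration diagnostics."""

    def __init__(self, msg, energies=None):
        super().__init__(msg)
        self.energies = energies or []


@dataclass
class SCFResult:
    geometry: MolecularGeometry
    e_hf: float                 # total RHF energy (Hartree)
    e_nuc: float
    mo_energies: np.ndarray     # canonical MO energies, ascending
    mo_coeff: np.ndarray        # AO x MO
    hcore: np.ndarray           # AO basis
    eri: np.ndarray             # AO basis, chemists' (ij|kl)
    overlap: np.ndarray
    n_occ: int                  # doubly occupied spatial orbitals
    density: np.ndarray = None  # converged AO density

    @property
    def n_orb(self) -> int:
        return len(self.mo_energies)

    def mo_hcore(self) -> np.ndarray:
        C = self.mo_coeff
        return C.T @ self.hcore @ C

    def mo_eri(self) -> np.ndarray:
        """(pq|rs) in the MO basis."""
        C = self.mo_coeff
        g = np.einsum("ijkl,ip->pjkl", self.eri, C, optimize=True)
        g = np.einsum("pjkl,jq->pqkl", g, C, optimize=True)
        g = np.einsum("pqkl,kr->pqrl", g, C, optimize=True)
        return np.einsum("pqrl,ls->pqrs", g, C, optimize=True)


def _ao_integrals(geom: MolecularGeometry):
    funcs = build_basis(geom.atoms, geom.coords_bohr, geom.basis)
    S, T, V = one_electron_integrals(funcs, geom.atomic_numbers,
                                     geom.coords_bohr)
    g = eri_tensor(funcs)
    return S, T + V, g


def _scf(geom, S, h, g, initial_density=None, conv_tol=1e-11,
         max_iter=200, diis_size=8):
    e_nuc = geom.nuclear_repulsion()
    n_occ = geom.n_electrons // 2
    w, U = np.linalg.eigh(S)
    X = U @ np.diag(w ** -0.5) @ U.T

    def fock(D):
        J = np.einsum("ijkl,kl->ij", g, D, optimize=True)
        K = np.einsum("ikjl,kl->ij", g, D, optimize=True)
        return h + J - 0.5 * K

    def density(F):
        eps, Cp = np.linalg.eigh(X.T @ F @ X)
        C = X @ Cp
        Cocc = C[:, :n_occ]
        return 2.0 * Cocc @ Cocc.T, eps, C

    if initial_density is None:
        # damped Roothaan phases settle the configuration before DIIS
        D, eps, C = density(h)
        for mix, n_it in ((0.3, 100), (0.5, 400)):
            e_old = np.inf
            for _ in range(n_it):
                Dn, eps, C = density(fock(D))
                D = (1.0 - mix) * D + mix * Dn
                e_el = 0.5 * np.sum(D * (h + fock(D)))
                if abs(e_el + e_nuc - e_old) < 1e-10:
                    break
                e_old = e_el + e_nuc
    else:
        D = initial_density

    energies = []
    diis_F, diis_err = [], []
    e_old = np.inf
    de, gnorm = np.inf, np.inf
    for _ in range(max_iter):
        F = fock(D)
        err = X.T @ (F @ D @ S - S @ D @ F) @ X
        diis_F.append(F)
        diis_err.append(err)
        if len(diis_F) > diis_size:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.sum(diis_err[i] * diis_err[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            c = np.linalg.lstsq(B, rhs, rcond=1e-14)[0][:m]
            F = sum(ci * Fi for ci, Fi in zip(c, diis_F))
        D, eps, C = density(F)
        e_el = 0.5 * np.sum(D * (h + fock(D)))
        energies.append(e_el + e_nuc)
        de = abs(e_el + e_nuc - e_old)
        gnorm = float(np.max(np.abs(diis_err[-1])))
        if de < conv_tol and gnorm < 1e-7:
            C = _purify_orbitals(geom, C, eps)
            return SCFResult(geom, e_el + e_nuc, e_nuc, eps, C, h, g, S,
                             n_occ, density=D)
        e_old = e_el + e_nuc
    raise SCFConvergenceError(
        f"SCF not converged in {max_iter} iterations (dE={de:.2e}, "
        f"|FDS-SDF|={gnorm:.2e})", energies)


def _purify_orbitals(geom: MolecularGeometry, C: np.ndarray,
                     eps: np.ndarray, tol: float = 1e-7) -> np.ndarray:
    """Resolve degenerate MO pairs onto molecule-frame symmetry axes.

    Degenerate canonical orbitals (e.g. the pi pair of a linear molecule)
    come out of the eigensolver in an arbitrary mixture, which hides the
    exact Z2 point-group structure of the qubit Hamiltonian.  Within each
    degenerate block we diagonalise the projector onto one molecule-frame
    transverse p direction, which separates the block into symmetry-pure
    partners in a rotation-covariant way.  Signs are then fixed so the
    largest-magnitude coefficient of every orbital is positive.
    """
    funcs = build_basis(geom.atoms, geom.coords_bohr, geom.basis)
    # molecule-frame axes: principal axis from the two most distant atoms
    R = geom.coords_bohr
    if len(R) >= 2:
        axis = R[-1] - R[0]
        nrm = np.linalg.norm(axis)
        axis = axis / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([0.0, 0.0, 1.0])
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    # projector onto the e1 component of every p shell
    nbf = len(funcs)
    P1 = np.zeros((nbf, nbf))
    k = 0
    while k < nbf:
        if funcs[k].lmn == (1, 0, 0) and k + 2 < nbf and \
                funcs[k + 1].lmn == (0, 1, 0) and funcs[k + 2].lmn == (0, 0, 1):
            v = np.zeros(nbf)
            v[k:k + 3] = e1
            P1 += np.outer(v, v)
            k += 3
        else:
            k += 1
    C = C.copy()
    i = 0
    M = C.shape[1]
    while i < M:
        j = i + 1
        while j < M and abs(eps[j] - eps[i]) < tol:
            j += 1
        if j - i > 1:
            block = C[:, i:j]
            m = block.T @ P1 @ block
            w, U = np.linalg.eigh(m)
            C[:, i:j] = block @ U
        i = j
    for p in range(M):
        k = int(np.argmax(np.abs(C[:, p])))
        if C[k, p] < 0:
            C[:, p] = -C[:, p]
    return C


#: bond length (Angstrom) from which diatomic continuation ladders start
_ANCHOR_R = 1.15
#: continuation step (Angstrom)
_LADDER_STEP = 0.1


def _diatomic_r(geom: MolecularGeometry) -> float | None:
    if len(geom.atoms) != 2:
        return None
    return float(np.linalg.norm(geom.coordinates[1] - geom.coordinates[0]))


def run_rhf(geom: MolecularGeometry, conv_tol: float = 1e-11,
            max_iter: int = 200, diis_size: int = 8,
            initial_density: np.ndarray | None = None) -> SCFResult:
    """Closed-shell restricted Hartree-Fock.

    ``initial_density`` warm-starts DIIS directly (used for scan
    continuation); otherwise a damped cold start is used, with an automatic
    continuation ladder for stretched homonuclear-style diatomics.
    """
    if geom.n_electrons % 2 != 0 or geom.multiplicity != 1:
        raise NotImplementedError(
            "only closed-shell singlet references are supported")
    S, h, g = _ao_integrals(geom)
    if initial_density is not None:
        return _scf(geom, S, h, g, initial_density, conv_tol, max_iter,
                    diis_size)
    r = _diatomic_r(geom)
    if r is None or r <= _ANCHOR_R + _LADDER_STEP:
        return _scf(geom, S, h, g, None, conv_tol, max_iter, diis_size)
    # continuation ladder from the equilibrium-region anchor
    unit = (geom.coordinates[1] - geom.coordinates[0]) / r
    rungs = list(np.arange(_ANCHOR_R, r, _LADDER_STEP)) + [r]
    D = None
    res = None
    for rk in rungs:
        gk = MolecularGeometry(
            geom.atoms,
            np.array([geom.coordinates[0], geom.coordinates[0] + unit * rk]),
            geom.charge, geom.multiplicity, geom.basis)
        Sk, hk, gk2 = (S, h, g) if rk == r else _ao_integrals(gk)
        res = _scf(gk, Sk, hk, gk2, D, conv_tol, max_iter, diis_size)
        D = res.density
    return res
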