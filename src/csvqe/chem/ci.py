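"""Determinant-based configuration interaction (FCI, CISD, CASCI).

Determinants are alpha/beta occupation bit-strings over spatial orbitals;
the Hamiltonian is assembled from spin-summed single-excitation operators
E_pq as sparse matrices, H = sum_pq h'_pq E_pq + 1/2 sum_rs A_rs E_rs with
A_rs = sum_pq (pq|rs) E_pq, which keeps the per-geometry build vectorised.
This route is independent of the qubit-Hamiltonian path and serves as its
cross-check (both must give the same ground energy).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["CIStringSpace", "fci_ground", "fci_energies", "cisd_ground",
           "casci_ground"]


def _bitcount(a):
    return np.bitwise_count(np.asarray(a, dtype=np.uint64)).astype(np.int64)


class CIStringSpace:
    """Occupation strings for one spin channel and their E_pq matrices."""

    def __init__(self, n_orb: int, n_elec: int):
        self.n_orb = n_orb
        self.n_elec = n_elec
        strs = []
        for occ in combinations(range(n_orb), n_elec):
            s = 0
            for o in occ:
                s |= 1 << o
            strs.append(s)
        self.strings = np.array(sorted(strs), dtype=np.uint64)
        self.index = {int(s): i for i, s in enumerate(self.strings)}
        self.dim = len(self.strings)
        self._single_cache: dict[tuple[int, int], sp.csr_matrix] = {}

    def single_excitation(self, p: int, q: int) -> sp.csr_matrix:
        """Matrix of a^dag_p a_q on the string space (fermionic signs)."""
        key = (p, q)
        if key in self._single_cache:
            return self._single_cache[key]
        I = self.strings
        occ_q = (I >> np.uint64(q)) & np.uint64(1)
        if p == q:
            mat = sp.diags(occ_q.astype(float)).tocsr()
        else:
            occ_p = (I >> np.uint64(p)) & np.uint64(1)
            ok = (occ_q == 1) & (occ_p == 0)
            src = np.flatnonzero(ok)
            I_ok = I[src]
            J = (I_ok ^ (np.uint64(1) << np.uint64(q))) | (np.uint64(1) << np.uint64(p))
            # sign: electrons strictly between p and q in the intermediate string
            lo, hi = (q, p) if q < p else (p, q)
            between = ((np.uint64(1) << np.uint64(hi)) - np.uint64(1)) & ~(
                (np.uint64(1) << np.uint64(lo + 1)) - np.uint64(1))
            nb = _bitcount((I_ok ^ (np.uint64(1) << np.uint64(q))) & between)
            sign = 1.0 - 2.0 * (nb % 2)
            dst = np.array([self.index[int(j)] for j in J])
            mat = sp.csr_matrix((sign, (dst, src)), shape=(self.dim, self.dim))
        self._single_cache[key] = mat
        return mat


class DeterminantSpace:
    """Direct-product alpha x beta determinant space.

    The CI Hamiltonian factorises over spin channels,

        H = H_ss(alpha) (x) 1  +  1 (x) H_ss(beta)
            + sum_pq T^a_pq (x) C^b_pq,

    where T_pq are single-excitation matrices on one spin-string space,
    H_ss collects the same-spin one- and two-electron parts and
    C_pq = sum_rs (pq|rs) T_rs couples the channels.  All blocks are tiny
    (string-space dimension), so assembly is a few hundred small dense
    matmuls plus sparse krons.
    """

    def __init__(self, n_orb: int, n_alpha: int, n_beta: int):
        self.n_orb = n_orb
        self.alpha = CIStringSpace(n_orb, n_alpha)
        self.beta = (self.alpha if n_beta == n_alpha
                     else CIStringSpace(n_orb, n_beta))
        self.dim = self.alpha.dim * self.beta.dim

    @staticmethod
    def _dense_t_stack(strs: CIStringSpace) -> np.ndarray:
        M = strs.n_orb
        T = np.zeros((M * M, strs.dim, strs.dim))
        for p in range(M):
            for q in range(M):
                T[p * M + q] = strs.single_excitation(p, q).toarray()
        return T

    @staticmethod
    def _same_spin_h(T: np.ndarray, hp: np.ndarray, C: np.ndarray):
        h1 = np.tensordot(hp.reshape(-1), T, axes=([0], [0]))
        h2 = 0.5 * np.einsum("kij,kjl->il", T, C, optimize=True)
        return h1 + h2

    def hamiltonian(self, h_mo: np.ndarray, g_mo: np.ndarray,
                    e_const: float = 0.0) -> sp.csr_matrix:
        """Sparse CI Hamiltonian for MO integrals (chemists' g)."""
        M = self.n_orb
        hp = h_mo - 0.5 * np.einsum("prrs->ps", g_mo)
        g2 = g_mo.reshape(M * M, M * M)
        Ta = self._dense_t_stack(self.alpha)
        Ca = np.tensordot(g2, Ta, axes=([1], [0]))
        if self.beta is self.alpha:
            Tb, Cb = Ta, Ca
        else:
            Tb = self._dense_t_stack(self.beta)
            Cb = np.tensordot(g2, Tb, axes=([1], [0]))
        Haa = self._same_spin_h(Ta, hp, Ca)
        Hbb = Haa if self.beta is self.alpha else self._same_spin_h(Tb, hp, Cb)
        Ia = sp.identity(self.alpha.dim, format="csr")
        Ib = sp.identity(self.beta.dim, format="csr")
        parts = [sp.kron(sp.csr_matrix(Haa), Ib, format="coo"),
                 sp.kron(Ia, sp.csr_matrix(Hbb), format="coo")]
        # cross-spin coupling; (p,q) and (q,p) blocks are transposes
        upper = []
        for p in range(M):
            for q in range(p, M):
                Tpq = self.alpha.single_excitation(p, q)
                Cpq = sp.csr_matrix(
                    np.where(np.abs(Cb[p * M + q]) > 1e-14, Cb[p * M + q], 0.0))
                if Tpq.nnz == 0 or Cpq.nnz == 0:
                    continue
                blk = sp.kron(Tpq, Cpq, format="coo")
                upper.append(blk)
                if q > p:
                    upper.append(blk.T)
        parts.extend(upper)
        rows = np.concatenate([b.row for b in parts])
        cols = np.concatenate([b.col for b in parts])
        data = np.concatenate([b.data for b in parts])
        H = sp.csr_matrix((data, (rows, cols)), shape=(self.dim, self.dim))
        if e_const:
            H = H + sp.identity(self.dim, format="csr") * e_const
        return H


def _lowest(H: sp.csr_matrix, k: int = 1, v0=None):
    dim = H.shape[0]
    if dim <= 600:
        w = np.linalg.eigvalsh(H.toarray())
        return w[:k]
    w = spla.eigsh(H, k=k, which="SA", v0=v0, return_eigenvectors=False,
                   maxiter=10000)
    return np.sort(w)


def _hf_vector(space: DeterminantSpace, n_occ_a: int, n_occ_b: int):
    hf_a = (1 << n_occ_a) - 1
    hf_b = (1 << n_occ_b) - 1
    v = np.zeros(space.dim)
    v[space.alpha.index[hf_a] * space.beta.dim + space.beta.index[hf_b]] = 1.0
    return v


def fci_ground(h_mo, g_mo, n_orb, n_alpha, n_beta, e_const=0.0,
               space: DeterminantSpace | None = None) -> float:
    """FCI ground-state energy (add e_const, e.g. nuclear repulsion)."""
    space = space or DeterminantSpace(n_orb, n_alpha, n_beta)
    H = space.hamiltonian(h_mo, g_mo)
    v0 = _hf_vector(space, n_alpha, n_beta)
    return float(_lowest(H, 1, v0)[0]) + e_const


def fci_energies(h_mo, g_mo, n_orb, n_alpha, n_beta, k, e_const=0.0):
    space = DeterminantSpace(n_orb, n_alpha, n_beta)
    H = space.hamiltonian(h_mo, g_mo)
    return np.asarray(_lowest(H, k)) + e_const


def cisd_ground(h_mo, g_mo, n_orb, n_alpha, n_beta, e_const=0.0,
                space: DeterminantSpace | None = None) -> float:
    """CISD: determinants within double excitations of the aufbau reference."""
    space = space or DeterminantSpace(n_orb, n_alpha, n_beta)
    hf_a = np.uint64((1 << n_alpha) - 1)
    hf_b = np.uint64((1 << n_beta) - 1)
    exc_a = n_alpha - _bitcount(space.alpha.strings & hf_a)
    exc_b = n_beta - _bitcount(space.beta.strings & hf_b)
    tot = exc_a[:, None] + exc_b[None, :]
    idx = np.flatnonzero(tot.reshape(-1) <= 2)
    H = space.hamiltonian(h_mo, g_mo)
    Hs = H[np.ix_(idx, idx)]
    return float(_lowest(Hs.tocsr(), 1)[0]) + e_const


def casci_ground(h_mo, g_mo, core: list[int], active: list[int],
                 n_active_elec: int, e_const=0.0) -> float:
    """CASCI: CI over ``active`` orbitals with ``core`` doubly occupied.

    ``h_mo``/``g_mo`` are full-space MO integrals in whatever orbital basis
    the caller chose (canonical or natural orbitals).
    """
    if n_active_elec % 2 != 0:
        raise ValueError("only spin-balanced active spaces are supported")
    core = list(core)
    active = list(active)
    # frozen-core energy and effective one-electron integrals
    e_core = 2.0 * sum(h_mo[c, c] for c in core)
    for c in core:
        for d in core:
            e_core += 2.0 * g_mo[c, c, d, d] - g_mo[c, d, d, c]
    h_eff = h_mo[np.ix_(active, active)].copy()
    for c in core:
        h_eff += (2.0 * g_mo[np.ix_(active, active, [c], [c])][:, :, 0, 0]
                  - g_mo[np.ix_(active, [c], [c], active)][:, 0, 0, :])
    g_act = g_mo[np.ix_(active, active, active, active)]
    na = n_active_elec // 2
    return fci_ground(h_eff, g_act, len(active), na, na,
                      e_const + e_core)
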