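"""Spin-orbital many-body perturbation theory and coupled cluster.

MP2, CCSD and the perturbative-triples correction in the standard
spin-orbital formulation (antisymmetrised physicists' integrals over a
restricted reference).  Spin orbitals are ordered interleaved,
s = 2 p + sigma with sigma = 0 (alpha), 1 (beta), matching the
Jordan-Wigner qubit ordering used elsewhere.

Amplitudes are exposed because they drive the contextual-subspace
stabilizer selection (MP2/CCSD excitation generators) and the MP2
natural-orbital active-space choice for CASCI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scf import SCFResult

__all__ = ["spin_orbital_integrals", "mp2", "ccsd", "ccsd_t",
           "mp2_natural_occupations", "CCResult"]


def spin_orbital_integrals(scf: SCFResult):
    """Interleaved spin-orbital h_pq and antisymmetrised <pq||rs>."""
    M = scf.n_orb
    h = scf.mo_hcore()
    g = scf.mo_eri()
    n = 2 * M
    hso = np.zeros((n, n))
    hso[0::2, 0::2] = h
    hso[1::2, 1::2] = h
    # physicists' <pq|rs> = (pr|qs) delta(sp,sr) delta(sq,ss)
    gso = np.zeros((n, n, n, n))
    for sp_ in (0, 1):
        for sq_ in (0, 1):
            gso[sp_::2, sq_::2, sp_::2, sq_::2] = g.transpose(0, 2, 1, 3)
    aso = gso - gso.transpose(0, 1, 3, 2)
    return hso, aso


def _slices(scf: SCFResult):
    n_occ_so = 2 * scf.n_occ
    n_so = 2 * scf.n_orb
    o = slice(0, n_occ_so)
    v = slice(n_occ_so, n_so)
    eps = np.repeat(scf.mo_energies, 2)
    return o, v, eps


@dataclass
class CCResult:
    e_corr: float
    t1: np.ndarray | None      # (o, v) spin-orbital amplitudes
    t2: np.ndarray             # (o, o, v, v)
    converged: bool = True
    n_iter: int = 0
    e_corr_mp2: float = 0.0


def mp2(scf: SCFResult) -> CCResult:
    """Second-order Moller-Plesset amplitudes and energy."""
    _, aso = spin_orbital_integrals(scf)
    o, v, eps = _slices(scf)
    eo, ev = eps[o], eps[v]
    D = (eo[:, None, None, None] + eo[None, :, None, None]
         - ev[None, None, :, None] - ev[None, None, None, :])
    t2 = aso[o, o, v, v] / D
    e = 0.25 * np.sum(t2 * aso[o, o, v, v])
    return CCResult(float(e), None, t2, True, 0, float(e))


def ccsd(scf: SCFResult, conv_tol: float = 1e-9, max_iter: int = 200,
         diis_size: int = 8) -> CCResult:
    """Spin-orbital CCSD with DIIS (Stanton-Gauss-Watts-Bartlett form)."""
    hso, w = spin_orbital_integrals(scf)
    o, v, eps = _slices(scf)
    no = 2 * scf.n_occ
    eo, ev = eps[o], eps[v]
    Dia = eo[:, None] - ev[None, :]
    Dijab = (eo[:, None, None, None] + eo[None, :, None, None]
             - ev[None, None, :, None] - ev[None, None, None, :])
    t1 = np.zeros((no, len(ev)))
    t2 = w[o, o, v, v] / Dijab
    e_mp2 = 0.25 * np.sum(t2 * w[o, o, v, v])

    woooo, wooov, woovv = w[o, o, o, o], w[o, o, o, v], w[o, o, v, v]
    wovov, wovvv, wvvvv = w[o, v, o, v], w[o, v, v, v], w[v, v, v, v]
    woovo = w[o, o, v, o]
    wvovv = w[v, o, v, v]
    wovvo = w[o, v, v, o]

    def tau(t1, t2):
        return t2 + np.einsum("ia,jb->ijab", t1, t1) \
                  - np.einsum("ib,ja->ijab", t1, t1)

    def tau_tilde(t1, t2):
        return t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                           - np.einsum("ib,ja->ijab", t1, t1))

    diis_t, diis_e = [], []
    e_old = 0.0
    for it in range(1, max_iter + 1):
        tt = tau_tilde(t1, t2)
        Fae = (-0.5 * np.einsum("mnaf,mnef->ae", tt, woovv)
               + np.einsum("mafe,mf->ae", wovvv, t1))
        Fmi = (0.5 * np.einsum("inef,mnef->mi", tt, woovv)
               + np.einsum("mnie,ne->mi", wooov, t1))
        Fme = np.einsum("mnef,nf->me", woovv, t1)

        Wmnij = (woooo
                 + np.einsum("je,mnie->mnij", t1, wooov)
                 - np.einsum("ie,mnje->mnij", t1, wooov)
                 + 0.25 * np.einsum("ijef,mnef->mnij", tau(t1, t2), woovv))
        Wabef = (wvvvv
                 - np.einsum("mb,amef->abef", t1, wvovv)
                 + np.einsum("ma,bmef->abef", t1, wvovv)
                 + 0.25 * np.einsum("mnab,mnef->abef", tau(t1, t2), woovv))
        Wmbej = (wovvo
                 + np.einsum("jf,mbef->mbej", t1, wovvv)
                 - np.einsum("nb,mnej->mbej", t1, woovo)
                 - np.einsum("jnfb,mnef->mbej", 0.5 * t2
                             + np.einsum("jf,nb->jnfb", t1, t1), woovv))

        # T1 residual
        r1 = (np.einsum("ie,ae->ia", t1, Fae)
              - np.einsum("ma,mi->ia", t1, Fmi)
              + np.einsum("imae,me->ia", t2, Fme)
              - np.einsum("nf,naif->ia", t1, wovov)
              - 0.5 * np.einsum("imef,maef->ia", t2, wovvv)
              - 0.5 * np.einsum("mnae,nmei->ia", t2, woovo))

        # T2 residual
        Fae_b = Fae - 0.5 * np.einsum("mb,me->be", t1, Fme)
        Fmi_b = Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme)
        r2 = woovv.copy()
        tmp = np.einsum("ijae,be->ijab", t2, Fae_b)
        r2 += tmp - tmp.transpose(0, 1, 3, 2)
        tmp = np.einsum("imab,mj->ijab", t2, Fmi_b)
        r2 -= tmp - tmp.transpose(1, 0, 2, 3)
        r2 += 0.5 * np.einsum("mnab,mnij->ijab", tau(t1, t2), Wmnij)
        r2 += 0.5 * np.einsum("ijef,abef->ijab", tau(t1, t2), Wabef)
        tmp = (np.einsum("imae,mbej->ijab", t2, Wmbej)
               - np.einsum("ie,ma,mbej->ijab", t1, t1, wovvo))
        tmp = tmp - tmp.transpose(0, 1, 3, 2)
        r2 += tmp - tmp.transpose(1, 0, 2, 3)
        # P(ij) t1_ie <ab||ej>  ;  P(ab) t1_ma <mb||ij>
        tmp = np.einsum("ie,abej->ijab", t1, w[v, v, v, o])
        r2 += tmp - tmp.transpose(1, 0, 2, 3)
        tmp = np.einsum("ma,mbij->ijab", t1, w[o, v, o, o])
        r2 -= tmp - tmp.transpose(0, 1, 3, 2)

        t1_new = r1 / Dia
        t2_new = r2 / Dijab

        # DIIS on stacked amplitudes
        vec = np.concatenate([t1_new.ravel(), t2_new.ravel()])
        err = np.concatenate([(t1_new - t1).ravel(), (t2_new - t2).ravel()])
        diis_t.append(vec)
        diis_e.append(err)
        if len(diis_t) > diis_size:
            diis_t.pop(0)
            diis_e.pop(0)
        if len(diis_t) > 1:
            m = len(diis_t)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.dot(diis_e[i], diis_e[j])
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                c = np.linalg.lstsq(B, rhs, rcond=1e-14)[0][:m]
                vec = sum(ci * vi for ci, vi in zip(c, diis_t))
            except np.linalg.LinAlgError:
                pass
        n1 = t1.size
        t1 = vec[:n1].reshape(t1.shape)
        t2 = vec[n1:].reshape(t2.shape)

        e_corr = (0.25 * np.sum(woovv * t2)
                  + 0.5 * np.einsum("ijab,ia,jb->", woovv, t1, t1))
        if abs(e_corr - e_old) < conv_tol and it > 2:
            return CCResult(float(e_corr), t1, t2, True, it, float(e_mp2))
        e_old = e_corr
    return CCResult(float(e_old), t1, t2, False, max_iter, float(e_mp2))


def ccsd_t(scf: SCFResult, cc: CCResult | None = None) -> tuple[float, CCResult]:
    """Perturbative triples correction; returns (E_(T), CCSD result)."""
    if cc is None:
        cc = ccsd(scf)
    _, w = spin_orbital_integrals(scf)
    o, v, eps = _slices(scf)
    eo, ev = eps[o], eps[v]
    t1, t2 = cc.t1, cc.t2
    woovv = w[o, o, v, v]
    wvoov = w[v, o, o, v]
    wooov = w[o, o, o, v]
    # D_ijk^abc
    D3 = (eo[:, None, None, None, None, None]
          + eo[None, :, None, None, None, None]
          + eo[None, None, :, None, None, None]
          - ev[None, None, None, :, None, None]
          - ev[None, None, None, None, :, None]
          - ev[None, None, None, None, None, :])

    def p_i_jk(x):  # antisymmetrise index i against (j, k)
        return x - x.transpose(1, 0, 2, 3, 4, 5) - x.transpose(2, 1, 0, 3, 4, 5)

    def p_a_bc(x):
        return x - x.transpose(0, 1, 2, 4, 3, 5) - x.transpose(0, 1, 2, 5, 4, 3)

    # connected triples:  P(i/jk) P(a/bc) [ sum_e t_jk^ae <ei||bc>
    #                                     - sum_m t_im^bc <ma||jk> ]
    x = (np.einsum("jkae,eibc->ijkabc", t2, w[v, o, v, v])
         - np.einsum("imbc,majk->ijkabc", t2, w[o, v, o, o]))
    t3c = p_a_bc(p_i_jk(x)) / D3
    # disconnected triples: P(i/jk) P(a/bc) t1_i^a <jk||bc>
    y = np.einsum("ia,jkbc->ijkabc", t1, woovv)
    t3d = p_a_bc(p_i_jk(y)) / D3
    e_t = np.sum(t3c * D3 * (t3c + t3d)) / 36.0
    return float(e_t), cc


def mp2_natural_occupations(scf: SCFResult):
    """Spatial natural occupations and orbitals from the unrelaxed MP2 1-RDM.

    Returns (occupations descending, C_natural as MO->NO rotation).
    """
    cc = mp2(scf)
    t2 = cc.t2
    no = 2 * scf.n_occ
    nv = 2 * scf.n_orb - no
    d_oo = -0.5 * np.einsum("ikab,jkab->ij", t2, t2)
    d_vv = 0.5 * np.einsum("ijac,ijbc->ab", t2, t2)
    D = np.zeros((2 * scf.n_orb, 2 * scf.n_orb))
    D[:no, :no] = np.eye(no) + d_oo
    D[no:, no:] = d_vv
    # fold interleaved spin orbitals back onto spatial MOs:
    # spatial p <-> spin orbitals (2p, 2p+1)
    spatial = D[0::2, 0::2] + D[1::2, 1::2]
    occ, U = np.linalg.eigh(spatial)
    return occ[::-1], U[:, ::-1]


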