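"""Gaussian integrals over contracted Cartesian functions (McMurchie-Davidson).

Overlap, kinetic, nuclear-attraction and two-electron repulsion integrals
for s/p shells (general in angular momentum up to the table sizes used).
The hot loops are compiled with numba when available; the same code runs
as plain Python otherwise.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

    _HAVE_NUMBA = False

_LMAX = 5  # table head-room: l + 2 shifts for kinetic


@njit(cache=True)
def _boys(n_max: int, T: float, out: np.ndarray) -> None:
    """Boys functions F_0..F_n_max(T) written into ``out``."""
    if T < 1e-13:
        for n in range(n_max + 1):
            out[n] = 1.0 / (2.0 * n + 1.0)
        return
    if T < 35.0:
        # series for F_{n_max}, then stable downward recursion
        s = 0.0
        term = 1.0 / (2.0 * n_max + 1.0)
        k = 0
        while True:
            s += term
            k += 1
            term *= 2.0 * T / (2.0 * n_max + 2.0 * k + 1.0)
            if term < 1e-17 * s or k > 200:
                break
        e = math.exp(-T)
        out[n_max] = e * s
        for n in range(n_max - 1, -1, -1):
            out[n] = (2.0 * T * out[n + 1] + e) / (2.0 * n + 1.0)
    else:
        out[0] = 0.5 * math.sqrt(math.pi / T)
        e = math.exp(-T)
        for n in range(n_max):
            out[n + 1] = ((2.0 * n + 1.0) * out[n] - e) / (2.0 * T)


@njit(cache=True)
def _hermite_e(i: int, j: int, a: float, b: float, AB: float,
               out: np.ndarray) -> None:
    """Hermite expansion coefficients E_t^{ij} for one Cartesian direction."""
    p = a + b
    mu = a * b / p
    tab = np.zeros((_LMAX + 1, _LMAX + 1, 2 * _LMAX + 2))
    tab[0, 0, 0] = math.exp(-mu * AB * AB)
    xpa = -b * AB / p
    xpb = a * AB / p
    for ii in range(i + 1):
        for jj in range(j + 1):
            if ii == 0 and jj == 0:
                continue
            if jj == 0:
                for t in range(ii + jj + 1):
                    v = xpa * tab[ii - 1, 0, t]
                    if t > 0:
                        v += tab[ii - 1, 0, t - 1] / (2.0 * p)
                    if t + 1 <= ii - 1:
                        v += (t + 1) * tab[ii - 1, 0, t + 1]
                    tab[ii, 0, t] = v
            else:
                for t in range(ii + jj + 1):
                    v = xpb * tab[ii, jj - 1, t]
                    if t > 0:
                        v += tab[ii, jj - 1, t - 1] / (2.0 * p)
                    if t + 1 <= ii + jj - 1:
                        v += (t + 1) * tab[ii, jj - 1, t + 1]
                    tab[ii, jj, t] = v
    for t in range(i + j + 1):
        out[t] = tab[i, j, t]


@njit(cache=True)
def _hermite_r(tmax: int, umax: int, vmax: int, alpha: float,
               X: float, Y: float, Z: float, out: np.ndarray) -> None:
    """Hermite Coulomb integrals R^0_{tuv} into out[t,u,v]."""
    ntot = tmax + umax + vmax
    T = alpha * (X * X + Y * Y + Z * Z)
    F = np.zeros(ntot + 1)
    _boys(ntot, T, F)
    # R^n_{000}
    Rn = np.zeros((ntot + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(ntot + 1):
        Rn[n, 0, 0, 0] = (-2.0 * alpha) ** n * F[n]
    for ttot in range(1, ntot + 1):
        for t in range(min(ttot, tmax) + 1):
            for u in range(min(ttot - t, umax) + 1):
                v = ttot - t - u
                if v < 0 or v > vmax:
                    continue
                for n in range(ntot - ttot + 1):
                    if t > 0:
                        val = X * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    elif u > 0:
                        val = Y * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = Z * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    Rn[n, t, u, v] = val
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                out[t, u, v] = Rn[0, t, u, v]


@njit(cache=True)
def _prim_overlap(a: float, la: int, ma: int, na: int, A: np.ndarray,
                  b: float, lb: int, mb: int, nb: int, B: np.ndarray) -> float:
    p = a + b
    ex = np.zeros(2 * _LMAX + 2)
    ey = np.zeros(2 * _LMAX + 2)
    ez = np.zeros(2 * _LMAX + 2)
    _hermite_e(la, lb, a, b, A[0] - B[0], ex)
    _hermite_e(ma, mb, a, b, A[1] - B[1], ey)
    _hermite_e(na, nb, a, b, A[2] - B[2], ez)
    return ex[0] * ey[0] * ez[0] * (math.pi / p) ** 1.5


@njit(cache=True)
def _prim_kinetic(a: float, la: int, ma: int, na: int, A: np.ndarray,
                  b: float, lb: int, mb: int, nb: int, B: np.ndarray) -> float:
    t0 = b * (2 * (lb + mb + nb) + 3) * _prim_overlap(a, la, ma, na, A,
                                                      b, lb, mb, nb, B)
    t1 = -2.0 * b * b * (
        _prim_overlap(a, la, ma, na, A, b, lb + 2, mb, nb, B)
        + _prim_overlap(a, la, ma, na, A, b, lb, mb + 2, nb, B)
        + _prim_overlap(a, la, ma, na, A, b, lb, mb, nb + 2, B)
    )
    t2 = 0.0
    if lb >= 2:
        t2 += lb * (lb - 1) * _prim_overlap(a, la, ma, na, A, b, lb - 2, mb, nb, B)
    if mb >= 2:
        t2 += mb * (mb - 1) * _prim_overlap(a, la, ma, na, A, b, lb, mb - 2, nb, B)
    if nb >= 2:
        t2 += nb * (nb - 1) * _prim_overlap(a, la, ma, na, A, b, lb, mb, nb - 2, B)
    return t0 + t1 - 0.5 * t2


@njit(cache=True)
def _prim_nuclear(a: float, la: int, ma: int, na: int, A: np.ndarray,
                  b: float, lb: int, mb: int, nb: int, B: np.ndarray,
                  C: np.ndarray) -> float:
    p = a + b
    P = (a * A + b * B) / p
    ex = np.zeros(2 * _LMAX + 2)
    ey = np.zeros(2 * _LMAX + 2)
    ez = np.zeros(2 * _LMAX + 2)
    _hermite_e(la, lb, a, b, A[0] - B[0], ex)
    _hermite_e(ma, mb, a, b, A[1] - B[1], ey)
    _hermite_e(na, nb, a, b, A[2] - B[2], ez)
    tmax, umax, vmax = la + lb, ma + mb, na + nb
    R = np.zeros((tmax + 1, umax + 1, vmax + 1))
    _hermite_r(tmax, umax, vmax, p, P[0] - C[0], P[1] - C[1], P[2] - C[2], R)
    s = 0.0
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                s += ex[t] * ey[u] * ez[v] * R[t, u, v]
    return 2.0 * math.pi / p * s


@njit(cache=True)
def _prim_eri(a: float, la: int, ma: int, na: int, A: np.ndarray,
              b: float, lb: int, mb: int, nb: int, B: np.ndarray,
              c: float, lc: int, mc: int, nc: int, C: np.ndarray,
              d: float, ld: int, md: int, nd: int, D: np.ndarray) -> float:
    p = a + b
    q = c + d
    alpha = p * q / (p + q)
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    e1x = np.zeros(2 * _LMAX + 2); e1y = np.zeros(2 * _LMAX + 2); e1z = np.zeros(2 * _LMAX + 2)
    e2x = np.zeros(2 * _LMAX + 2); e2y = np.zeros(2 * _LMAX + 2); e2z = np.zeros(2 * _LMAX + 2)
    _hermite_e(la, lb, a, b, A[0] - B[0], e1x)
    _hermite_e(ma, mb, a, b, A[1] - B[1], e1y)
    _hermite_e(na, nb, a, b, A[2] - B[2], e1z)
    _hermite_e(lc, ld, c, d, C[0] - D[0], e2x)
    _hermite_e(mc, md, c, d, C[1] - D[1], e2y)
    _hermite_e(nc, nd, c, d, C[2] - D[2], e2z)
    t1, u1, v1 = la + lb, ma + mb, na + nb
    t2, u2, v2 = lc + ld, mc + md, nc + nd
    R = np.zeros((t1 + t2 + 1, u1 + u2 + 1, v1 + v2 + 1))
    _hermite_r(t1 + t2, u1 + u2, v1 + v2, alpha,
               P[0] - Q[0], P[1] - Q[1], P[2] - Q[2], R)
    s = 0.0
    for t in range(t1 + 1):
        for u in range(u1 + 1):
            for v in range(v1 + 1):
                e1 = e1x[t] * e1y[u] * e1z[v]
                if e1 == 0.0:
                    continue
                for tt in range(t2 + 1):
                    for uu in range(u2 + 1):
                        for vv in range(v2 + 1):
                            e2 = e2x[tt] * e2y[uu] * e2z[vv]
                            if e2 == 0.0:
                                continue
                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                            s += e1 * e2 * sgn * R[t + tt, u + uu, v + vv]
    return s * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))


@njit(cache=True)
def _contracted_1e(kind: int, exps1, coefs1, lmn1, A,
                   exps2, coefs2, lmn2, B, C) -> float:
    s = 0.0
    for i in range(len(exps1)):
        for j in range(len(exps2)):
            w = coefs1[i] * coefs2[j]
            if kind == 0:
                s += w * _prim_overlap(exps1[i], lmn1[0], lmn1[1], lmn1[2], A,
                                       exps2[j], lmn2[0], lmn2[1], lmn2[2], B)
            elif kind == 1:
                s += w * _prim_kinetic(exps1[i], lmn1[0], lmn1[1], lmn1[2], A,
                                       exps2[j], lmn2[0], lmn2[1], lmn2[2], B)
            else:
                s += w * _prim_nuclear(exps1[i], lmn1[0], lmn1[1], lmn1[2], A,
                                       exps2[j], lmn2[0], lmn2[1], lmn2[2], B, C)
    return s


@njit(cache=True)
def _eri_tensor_kernel(nbf, exps, coefs, nprim, lmn, centers):
    g = np.zeros((nbf, nbf, nbf, nbf))
    for i in range(nbf):
        for j in range(i + 1):
            for k in range(nbf):
                for l in range(k + 1):
                    if i * (i + 1) // 2 + j < k * (k + 1) // 2 + l:
                        continue
                    val = 0.0
                    for pi in range(nprim[i]):
                        for pj in range(nprim[j]):
                            for pk in range(nprim[k]):
                                for pl in range(nprim[l]):
                                    w = (coefs[i, pi] * coefs[j, pj]
                                         * coefs[k, pk] * coefs[l, pl])
                                    val += w * _prim_eri(
                                        exps[i, pi], lmn[i, 0], lmn[i, 1], lmn[i, 2], centers[i],
                                        exps[j, pj], lmn[j, 0], lmn[j, 1], lmn[j, 2], centers[j],
                                        exps[k, pk], lmn[k, 0], lmn[k, 1], lmn[k, 2], centers[k],
                                        exps[l, pl], lmn[l, 0], lmn[l, 1], lmn[l, 2], centers[l],
                                    )
                    for a, b in ((i, j), (j, i)):
                        for c, d in ((k, l), (l, k)):
                            g[a, b, c, d] = val
                            g[c, d, a, b] = val
    return g


# ----------------------------------------------------------------- public API

def _pack(funcs):
    nbf = len(funcs)
    maxp = max(len(f.exps) for f in funcs)
    exps = np.zeros((nbf, maxp))
    coefs = np.zeros((nbf, maxp))
    nprim = np.zeros(nbf, dtype=np.int64)
    lmn = np.zeros((nbf, 3), dtype=np.int64)
    centers = np.zeros((nbf, 3))
    for k, f in enumerate(funcs):
        npk = len(f.exps)
        nprim[k] = npk
        exps[k, :npk] = f.exps
        coefs[k, :npk] = f.coefs
        lmn[k] = f.lmn
        centers[k] = f.center
    return nbf, exps, coefs, nprim, lmn, centers


def overlap_single(f1, f2) -> float:
    A = np.asarray(f1.center, float)
    B = np.asarray(f2.center, float)
    s = 0.0
    for a, ca in zip(f1.exps, f1.coefs):
        for b, cb in zip(f2.exps, f2.coefs):
            s += ca * cb * _prim_overlap(a, f1.lmn[0], f1.lmn[1], f1.lmn[2], A,
                                         b, f2.lmn[0], f2.lmn[1], f2.lmn[2], B)
    return s


def one_electron_integrals(funcs, atoms_Z, coords_bohr):
    """Overlap S, kinetic T and nuclear-attraction V matrices."""
    nbf = len(funcs)
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    dummy = np.zeros(3)
    for i in range(nbf):
        for j in range(i + 1):
            fi, fj = funcs[i], funcs[j]
            li = np.asarray(fi.lmn, np.int64)
            lj = np.asarray(fj.lmn, np.int64)
            S[i, j] = S[j, i] = _contracted_1e(
                0, fi.exps, fi.coefs, li, fi.center, fj.exps, fj.coefs, lj,
                fj.center, dummy)
            T[i, j] = T[j, i] = _contracted_1e(
                1, fi.exps, fi.coefs, li, fi.center, fj.exps, fj.coefs, lj,
                fj.center, dummy)
            v = 0.0
            for Z, C in zip(atoms_Z, coords_bohr):
                v -= Z * _contracted_1e(
                    2, fi.exps, fi.coefs, li, fi.center, fj.exps, fj.coefs,
                    lj, fj.center, np.asarray(C, float))
            V[i, j] = V[j, i] = v
    return S, T, V


def eri_tensor(funcs) -> np.ndarray:
    """Full (ij|kl) chemists'-notation two-electron tensor."""
    nbf, exps, coefs, nprim, lmn, centers = _pack(funcs)
    return _eri_tensor_kernel(nbf, exps, coefs, nprim, lmn, centers)
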