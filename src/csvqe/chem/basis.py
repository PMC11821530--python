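"""STO-3G basis-set data and shell expansion.

Exponents and contraction coefficients are the standard published STO-3G
parameters (Hehre, Stewart & Pople scheme) for the elements needed at desk
scale.  Coefficients refer to normalised primitives; contracted functions
are renormalised numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# element -> list of (l, exponents, coefficients); l=0 s, l=1 p.
# "sp" shells are stored as separate s and p entries sharing exponents.
STO3G: dict[str, list[tuple[int, list[float], list[float]]]] = {
    "H": [
        (0, [3.425250914, 0.6239137298, 0.1688554040],
            [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "He": [
        (0, [6.36242139, 1.158922999, 0.3136497915],
            [0.1543289673, 0.5353281423, 0.4446345422]),
    ],
    "Li": [
        (0, [16.11957475, 2.936200663, 0.7946504870],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [0.6362897469, 0.1478600533, 0.0480886784],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [0.6362897469, 0.1478600533, 0.0480886784],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "C": [
        (0, [71.61683735, 13.04509632, 3.530512160],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [2.941249355, 0.6834830964, 0.2222899159],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [2.941249355, 0.6834830964, 0.2222899159],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "N": [
        (0, [99.10616896, 18.05231239, 4.885660238],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [3.780455879, 0.8784966449, 0.2857143744],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [3.780455879, 0.8784966449, 0.2857143744],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
    "O": [
        (0, [130.7093214, 23.80886605, 6.443608313],
            [0.1543289673, 0.5353281423, 0.4446345422]),
        (0, [5.033151319, 1.169596125, 0.3803889600],
            [-0.09996722919, 0.3995128261, 0.7001154689]),
        (1, [5.033151319, 1.169596125, 0.3803889600],
            [0.1559162750, 0.6076837186, 0.3919573931]),
    ],
}

ATOMIC_NUMBER = {"H": 1, "He": 2, "Li": 3, "C": 6, "N": 7, "O": 8}

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903


@dataclass
class BasisFunction:
    """A contracted Cartesian Gaussian: sum_k c_k N_k exp(-a_k r^2) x^i y^j z^k."""

    center: np.ndarray          # bohr
    lmn: tuple[int, int, int]   # Cartesian powers
    exps: np.ndarray
    coefs: np.ndarray           # includes primitive + contraction normalisation


def _primitive_norm(a: float, lmn: tuple[int, int, int]) -> float:
    l, m, n = lmn

    def df(k):  # (2k-1)!!
        return 1 if k <= 0 else np.prod(np.arange(2 * k - 1, 0, -2))

    pre = (2.0 * a / np.pi) ** 0.75
    num = (4.0 * a) ** ((l + m + n) / 2.0)
    den = np.sqrt(float(df(l) * df(m) * df(n)))
    return pre * num / den


def build_basis(atoms: list[str], coords_bohr: np.ndarray,
                basis: str = "sto-3g") -> list[BasisFunction]:
    if basis.lower() not in ("sto-3g", "sto3g"):
        raise ValueError(f"unsupported basis {basis!r}; only STO-3G is bundled")
    funcs: list[BasisFunction] = []
    for sym, xyz in zip(atoms, coords_bohr):
        if sym not in STO3G:
            raise ValueError(f"no STO-3G parameters bundled for element {sym!r}")
        for l, exps, coefs in STO3G[sym]:
            exps = np.asarray(exps, float)
            coefs = np.asarray(coefs, float)
            lmns = [(0, 0, 0)] if l == 0 else [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
            for lmn in lmns:
                cn = coefs * np.array([_primitive_norm(a, lmn) for a in exps])
                bf = BasisFunction(np.asarray(xyz, float), lmn, exps, cn)
                # renormalise the contracted function
                from .integrals import overlap_single
                s = overlap_single(bf, bf)
                bf.coefs = bf.coefs / np.sqrt(s)
                funcs.append(bf)
    return funcs
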