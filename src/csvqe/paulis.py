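"""Symplectic Pauli-operator algebra.

Operators are weighted sums of n-qubit Pauli strings stored in binary
symplectic form: a string is a pair of bit-masks ``(x, z)`` where bit ``k``
of ``x`` (``z``) records an X (Z) factor on qubit ``k``; a qubit with both
bits set carries Y.  The represented operator for one term is

    O(x, z) = i^{|x & z|} X^x Z^z,

which is Hermitian, so Hermitian sums have real coefficients.  Masks are
little-endian internally (bit k <-> qubit k) but all text I/O uses explicit
string form ("XZIY", qubit 0 leftmost) so no endianness leaks out.

The class:`PauliSum` is vectorised over terms (numpy uint64 masks), which
keeps molecular Hamiltonians with thousands of terms cheap to manipulate;
:class:`PauliTerm` is a scalar convenience view used by the algebraic
front-end and the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "PauliTerm",
    "PauliSum",
    "commutes",
    "qubit_wise_commutes",
    "is_noncontextual",
    "noncontextual_clique_partition",
    "random_pauli_sum",
    "read_pauli_file",
    "write_pauli_file",
]

_CHAR_TO_BITS = {"I": (0, 0), "X": (1, 0), "Z": (0, 1), "Y": (1, 1)}
_BITS_TO_CHAR = {v: k for k, v in _CHAR_TO_BITS.items()}

#: coefficients below this magnitude are dropped during canonicalization
COEFF_TOL = 1e-12


def _popcount(a):
    return np.bitwise_count(np.asarray(a, dtype=np.uint64))


def _string_to_masks(s: str) -> tuple[int, int]:
    x = z = 0
    for k, ch in enumerate(s):
        try:
            bx, bz = _CHAR_TO_BITS[ch]
        except KeyError:
            raise ValueError(f"invalid Pauli character {ch!r} in {s!r}")
        x |= bx << k
        z |= bz << k
    return x, z


def _masks_to_string(x: int, z: int, n: int) -> str:
    return "".join(_BITS_TO_CHAR[((x >> k) & 1, (z >> k) & 1)] for k in range(n))


def _product_phase(x1, z1, x2, z2):
    """i-exponent (mod 4) of O(x1,z1)O(x2,z2) relative to O(x1^x2, z1^z2)."""
    x1 = np.asarray(x1, dtype=np.uint64)
    z1 = np.asarray(z1, dtype=np.uint64)
    x2 = np.asarray(x2, dtype=np.uint64)
    z2 = np.asarray(z2, dtype=np.uint64)
    e = (
        _popcount(x1 & z1).astype(np.int64)
        + _popcount(x2 & z2).astype(np.int64)
        - _popcount((x1 ^ x2) & (z1 ^ z2)).astype(np.int64)
        + 2 * _popcount(z1 & x2).astype(np.int64)
    )
    return np.mod(e, 4)

_I_POWERS = np.array([1.0 + 0.0j, 1.0j, -1.0 + 0.0j, -1.0j])


@dataclass
class PauliTerm:
    """A single weighted Pauli string."""

    coefficient: complex
    x_mask: int
    z_mask: int
    n_qubits: int

    @classmethod
    def from_string(cls, s: str, coefficient: complex = 1.0) -> "PauliTerm":
        x, z = _string_to_masks(s)
        return cls(coefficient, x, z, len(s))

    @property
    def is_identity(self) -> bool:
        return self.x_mask == 0 and self.z_mask == 0

    def pauli_string(self) -> str:
        return _masks_to_string(self.x_mask, self.z_mask, self.n_qubits)

    def multiply(self, other: "PauliTerm") -> "PauliTerm":
        if self.n_qubits != other.n_qubits:
            raise ValueError(
                f"mask length mismatch: {self.n_qubits} vs {other.n_qubits}"
            )
        ph = _I_POWERS[int(_product_phase(self.x_mask, self.z_mask,
                                          other.x_mask, other.z_mask))]
        return PauliTerm(
            self.coefficient * other.coefficient * ph,
            self.x_mask ^ other.x_mask,
            self.z_mask ^ other.z_mask,
            self.n_qubits,
        )

    __mul__ = multiply

    def commutes(self, other: "PauliTerm") -> bool:
        return commutes(self, other)

    def to_sum(self) -> "PauliSum":
        return PauliSum(
            np.array([self.x_mask], dtype=np.uint64),
            np.array([self.z_mask], dtype=np.uint64),
            np.array([self.coefficient], dtype=complex),
            self.n_qubits,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"PauliTerm({self.coefficient:+.6g} * {self.pauli_string()})"


def commutes(a: PauliTerm, b: PauliTerm) -> bool:
    """True iff the two Pauli strings commute (symplectic form vanishes)."""
    if a.n_qubits != b.n_qubits:
        raise ValueError(f"mask length mismatch: {a.n_qubits} vs {b.n_qubits}")
    s = _popcount(a.x_mask & b.z_mask) + _popcount(a.z_mask & b.x_mask)
    return int(s) % 2 == 0


def qubit_wise_commutes(a: PauliTerm, b: PauliTerm) -> bool:
    """True iff on every qubit the factors agree or at least one is identity."""
    if a.n_qubits != b.n_qubits:
        raise ValueError(f"mask length mismatch: {a.n_qubits} vs {b.n_qubits}")
    s1 = a.x_mask | a.z_mask
    s2 = b.x_mask | b.z_mask
    o = s1 & s2
    return ((a.x_mask ^ b.x_mask) & o) == 0 and ((a.z_mask ^ b.z_mask) & o) == 0


class PauliSum:
    """Weighted sum of Pauli strings in vectorised symplectic form.

    After :meth:`canonicalize` no two terms share a mask pair and
    coefficients below ``COEFF_TOL`` are removed.
    """

    def __init__(self, x, z, coeffs, n_qubits: int, canonicalize: bool = True):
        self.x = np.atleast_1d(np.asarray(x, dtype=np.uint64))
        self.z = np.atleast_1d(np.asarray(z, dtype=np.uint64))
        self.coeffs = np.atleast_1d(np.asarray(coeffs, dtype=complex))
        if not (len(self.x) == len(self.z) == len(self.coeffs)):
            raise ValueError("mask/coefficient arrays must have equal length")
        if n_qubits > 64:
            raise ValueError("at most 64 qubits supported")
        self.n_qubits = int(n_qubits)
        if canonicalize:
            self.canonicalize()

    # ------------------------------------------------------------------ build
    @classmethod
    def from_terms(cls, terms: Iterable[PauliTerm], n_qubits: int | None = None):
        terms = list(terms)
        if not terms:
            if n_qubits is None:
                raise ValueError("n_qubits required for an empty sum")
            return cls.zero(n_qubits)
        n = terms[0].n_qubits if n_qubits is None else n_qubits
        for t in terms:
            if t.n_qubits != n:
                raise ValueError("inconsistent term lengths")
        return cls(
            [t.x_mask for t in terms],
            [t.z_mask for t in terms],
            [t.coefficient for t in terms],
            n,
        )

    @classmethod
    def from_strings(cls, data: dict[str, complex] | Sequence[tuple[str, complex]],
                     n_qubits: int | None = None):
        items = data.items() if isinstance(data, dict) else data
        terms = [PauliTerm.from_string(s, c) for s, c in items]
        return cls.from_terms(terms, n_qubits)

    @classmethod
    def zero(cls, n_qubits: int):
        return cls(np.empty(0, np.uint64), np.empty(0, np.uint64),
                   np.empty(0, complex), n_qubits)

    @classmethod
    def identity(cls, n_qubits: int, coefficient: complex = 1.0):
        return cls([0], [0], [coefficient], n_qubits)

    def copy(self) -> "PauliSum":
        return PauliSum(self.x.copy(), self.z.copy(), self.coeffs.copy(),
                        self.n_qubits, canonicalize=False)

    # ------------------------------------------------------------- properties
    @property
    def n_terms(self) -> int:
        return len(self.coeffs)

    def __len__(self) -> int:
        return self.n_terms

    def __iter__(self) -> Iterator[PauliTerm]:
        for k in range(self.n_terms):
            yield PauliTerm(complex(self.coeffs[k]), int(self.x[k]),
                            int(self.z[k]), self.n_qubits)

    def terms(self) -> list[PauliTerm]:
        return list(self)

    def pauli_strings(self) -> list[str]:
        return [_masks_to_string(int(x), int(z), self.n_qubits)
                for x, z in zip(self.x, self.z)]

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return bool(np.all(np.abs(self.coeffs.imag) < tol))

    def l1_norm(self) -> float:
        """Sum of coefficient magnitudes, Lambda = sum_i |h_i|."""
        return float(np.sum(np.abs(self.coeffs)))

    def identity_coefficient(self) -> complex:
        m = (self.x == 0) & (self.z == 0)
        return complex(self.coeffs[m].sum()) if m.any() else 0.0j

    # --------------------------------------------------------------- algebra
    def canonicalize(self, tol: float = COEFF_TOL) -> "PauliSum":
        """Merge duplicate masks and drop negligible coefficients, in place."""
        if self.n_terms == 0:
            return self
        order = np.lexsort((self.z, self.x))
        x, z, c = self.x[order], self.z[order], self.coeffs[order]
        new_group = np.empty(len(x), dtype=bool)
        new_group[0] = True
        np.logical_or(x[1:] != x[:-1], z[1:] != z[:-1], out=new_group[1:])
        idx = np.flatnonzero(new_group)
        csum = np.add.reduceat(c, idx)
        keep = np.abs(csum) > tol
        self.x, self.z, self.coeffs = x[idx][keep], z[idx][keep], csum[keep]
        return self

    def __add__(self, other):
        if np.isscalar(other):
            other = PauliSum.identity(self.n_qubits, other)
        if self.n_qubits != other.n_qubits:
            raise ValueError("qubit-count mismatch")
        return PauliSum(
            np.concatenate([self.x, other.x]),
            np.concatenate([self.z, other.z]),
            np.concatenate([self.coeffs, other.coeffs]),
            self.n_qubits,
        )

    __radd__ = __add__

    def __sub__(self, other):
        return self + (other * -1.0 if isinstance(other, PauliSum) else -other)

    def __mul__(self, other):
        if np.isscalar(other):
            return PauliSum(self.x, self.z, self.coeffs * other,
                            self.n_qubits, canonicalize=False)
        if isinstance(other, PauliTerm):
            other = other.to_sum()
        if self.n_qubits != other.n_qubits:
            raise ValueError("qubit-count mismatch")
        # outer product of terms, vectorised
        x1 = np.repeat(self.x, other.n_terms)
        z1 = np.repeat(self.z, other.n_terms)
        c1 = np.repeat(self.coeffs, other.n_terms)
        x2 = np.tile(other.x, self.n_terms)
        z2 = np.tile(other.z, self.n_terms)
        c2 = np.tile(other.coeffs, self.n_terms)
        ph = _I_POWERS[_product_phase(x1, z1, x2, z2)]
        return PauliSum(x1 ^ x2, z1 ^ z2, c1 * c2 * ph, self.n_qubits)

    __rmul__ = lambda self, other: self.__mul__(other)

    def rotated(self, P: "PauliTerm", theta: float) -> "PauliSum":
        """U H U^dag with U = exp(i theta/2 P) for a Pauli rotation generator.

        Terms commuting with P are unchanged; anticommuting terms map to
        cos(theta) Q + i sin(theta) P*Q.  At theta = +-pi/2 this is a
        Clifford map (Pauli terms to Pauli terms).
        """
        mask = self.commutes_with_term(P.x_mask, P.z_mask)
        if mask.all():
            return self.copy()
        ax, az, ac = self.x[~mask], self.z[~mask], self.coeffs[~mask]
        c, s = np.cos(theta), np.sin(theta)
        px = np.uint64(P.x_mask)
        pz = np.uint64(P.z_mask)
        ph = _I_POWERS[_product_phase(np.full_like(ax, px),
                                      np.full_like(az, pz), ax, az)]
        new_x = np.concatenate([self.x[mask], ax, ax ^ px])
        new_z = np.concatenate([self.z[mask], az, az ^ pz])
        new_c = np.concatenate([
            self.coeffs[mask], ac * c,
            1j * s * P.coefficient * ac * ph,
        ])
        return PauliSum(new_x, new_z, new_c, self.n_qubits)

    def commutes_with_term(self, x: int, z: int) -> np.ndarray:
        """Boolean array: which terms commute with the mask pair (x, z)."""
        s = _popcount(self.x & np.uint64(z)) + _popcount(self.z & np.uint64(x))
        return (s % 2) == 0

    def restrict_to_qubits(self, qubits: Sequence[int]) -> "PauliSum":
        """Keep only the listed qubit positions (terms must be identity
        elsewhere is *not* required: factors on dropped qubits are discarded,
        so callers must ensure they are identity)."""
        nx = np.zeros_like(self.x)
        nz = np.zeros_like(self.z)
        for new_k, old_k in enumerate(qubits):
            bit = np.uint64(1) << np.uint64(old_k)
            nx |= ((self.x & bit) >> np.uint64(old_k)) << np.uint64(new_k)
            nz |= ((self.z & bit) >> np.uint64(old_k)) << np.uint64(new_k)
        return PauliSum(nx, nz, self.coeffs.copy(), len(qubits))

    # --------------------------------------------------------------- matrices
    def _index_masks(self):
        """Masks translated to computational-basis index bit positions
        (qubit 0 is the most significant index bit)."""
        n = self.n_qubits
        xi = np.zeros_like(self.x)
        zi = np.zeros_like(self.z)
        for k in range(n):
            src = np.uint64(1) << np.uint64(k)
            dst = np.uint64(n - 1 - k)
            xi |= ((self.x & src) >> np.uint64(k)) << dst
            zi |= ((self.z & src) >> np.uint64(k)) << dst
        return xi, zi

    def to_sparse_matrix(self) -> sp.csr_matrix:
        """Dense/sparse matrix in the computational basis (n <= ~16)."""
        n = self.n_qubits
        if n > 16:
            raise ValueError("explicit matrix limited to 16 qubits")
        dim = 1 << n
        xi, zi = self._index_masks()
        b = np.arange(dim, dtype=np.uint64)
        rows, cols, data = [], [], []
        for k in range(self.n_terms):
            phase = _I_POWERS[int(_popcount(xi[k] & zi[k])) % 4]
            signs = 1.0 - 2.0 * (_popcount(b & zi[k]).astype(np.int64) % 2)
            rows.append(b ^ xi[k])
            cols.append(b)
            data.append(self.coeffs[k] * phase * signs)
        if not rows:
            return sp.csr_matrix((dim, dim), dtype=complex)
        return sp.csr_matrix(
            (np.concatenate(data),
             (np.concatenate(rows).astype(np.int64),
              np.concatenate(cols).astype(np.int64))),
            shape=(dim, dim),
        )

    def to_dense_matrix(self) -> np.ndarray:
        return self.to_sparse_matrix().toarray()

    def apply_to_statevector(self, v: np.ndarray) -> np.ndarray:
        """H @ v without forming a matrix (works to 30+ qubits in principle)."""
        dim = 1 << self.n_qubits
        if v.shape[0] != dim:
            raise ValueError("statevector dimension mismatch")
        xi, zi = self._index_masks()
        b = np.arange(dim, dtype=np.uint64)
        out = np.zeros(dim, dtype=complex)
        # group terms sharing an X-mask: one permutation, combined diagonal
        order = np.argsort(xi, kind="stable")
        k0 = 0
        xs, zs, cs = xi[order], zi[order], self.coeffs[order]
        while k0 < len(xs):
            k1 = k0
            while k1 < len(xs) and xs[k1] == xs[k0]:
                k1 += 1
            w = np.zeros(dim, dtype=complex)
            for k in range(k0, k1):
                phase = _I_POWERS[int(_popcount(xs[k] & zs[k])) % 4]
                signs = 1.0 - 2.0 * (_popcount(b & zs[k]).astype(np.int64) % 2)
                w += cs[k] * phase * signs
            out[(b ^ xs[k0]).astype(np.int64)] += w * v
            k0 = k1
        return out

    def expectation(self, v: np.ndarray) -> float:
        return float(np.real(np.vdot(v, self.apply_to_statevector(v))))

    def to_linear_operator(self) -> spla.LinearOperator:
        """Matrix-free Hermitian operator; scales past explicit matrices."""
        dim = 1 << self.n_qubits
        xi, zi = self._index_masks()
        b = np.arange(dim, dtype=np.uint64)
        order = np.argsort(xi, kind="stable")
        xs, zs, cs = xi[order], zi[order], self.coeffs[order]
        bounds = [0]
        for k in range(1, len(xs) + 1):
            if k == len(xs) or xs[k] != xs[k - 1]:
                bounds.append(k)
        n_groups = len(bounds) - 1
        cache_weights = n_groups * dim * 16 < 1.5e9

        def group_weight(k0, k1):
            w = np.zeros(dim, dtype=complex)
            for k in range(k0, k1):
                phase = _I_POWERS[int(_popcount(xs[k] & zs[k])) % 4]
                signs = 1.0 - 2.0 * (_popcount(b & zs[k]).astype(np.int64) % 2)
                w += cs[k] * phase * signs
            return w

        if cache_weights:
            groups = [((b ^ xs[bounds[i]]).astype(np.int64),
                       group_weight(bounds[i], bounds[i + 1]))
                      for i in range(n_groups)]

            def matvec(v):
                v = np.asarray(v).reshape(-1)
                out = np.zeros(dim, dtype=complex)
                for perm, w in groups:
                    out[perm] += w * v
                return out
        else:
            def matvec(v):
                v = np.asarray(v).reshape(-1)
                out = np.zeros(dim, dtype=complex)
                for i in range(n_groups):
                    k0, k1 = bounds[i], bounds[i + 1]
                    perm = (b ^ xs[k0]).astype(np.int64)
                    out[perm] += group_weight(k0, k1) * v
                return out

        return spla.LinearOperator((dim, dim), matvec=matvec, dtype=complex)

    def ground_energy_exact(self, k_lowest: int = 1):
        """Lowest eigenvalue by exact (sparse or matrix-free) diagonalization.

        The Hamiltonian must be Hermitian.  Explicit sparse matrices are
        used to ~13 qubits; beyond that a matrix-free Lanczos is used.
        """
        if not self.is_hermitian(tol=1e-8):
            raise ValueError("ground_energy_exact requires a Hermitian sum")
        n = self.n_qubits
        dim = 1 << n
        if self.n_terms == 0:
            return 0.0
        if dim <= 64:
            w = np.linalg.eigvalsh(self.to_dense_matrix())
            return float(w[0]) if k_lowest == 1 else w[:k_lowest]
        k = max(k_lowest, 1)
        if n <= 13:
            mat = self.to_sparse_matrix()
            mat = (mat + mat.getH()) * 0.5
            w = spla.eigsh(mat, k=k, which="SA", return_eigenvectors=False,
                           maxiter=5000)
        else:
            op = self.to_linear_operator()
            w = spla.eigsh(op, k=k, which="SA", return_eigenvectors=False,
                           maxiter=5000, tol=1e-9)
        w = np.sort(w)
        return float(w[0]) if k_lowest == 1 else w[:k_lowest]

    def ground_state_exact(self) -> tuple[float, np.ndarray]:
        if not self.is_hermitian(tol=1e-8):
            raise ValueError("requires a Hermitian sum")
        dim = 1 << self.n_qubits
        if dim <= 64:
            w, v = np.linalg.eigh(self.to_dense_matrix())
            return float(w[0]), v[:, 0]
        mat = self.to_sparse_matrix()
        mat = (mat + mat.getH()) * 0.5
        w, v = spla.eigsh(mat, k=1, which="SA", maxiter=5000)
        return float(w[0]), v[:, 0]

    def __repr__(self) -> str:  # pragma: no cover
        if self.n_terms <= 8:
            body = " ".join(
                f"{c.real:+.4g}{'' if abs(c.imag) < 1e-12 else f'{c.imag:+.4g}j'}*{s}"
                for c, s in zip(self.coeffs, self.pauli_strings())
            )
            return f"PauliSum[{self.n_qubits}q]({body})"
        return f"PauliSum[{self.n_qubits} qubits, {self.n_terms} terms]"


# ---------------------------------------------------------------- contextuality

def _pairwise_commute(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    """m x m boolean commutation table for mask arrays."""
    ax = x[:, None] & z[None, :]
    az = z[:, None] & x[None, :]
    s = _popcount(ax).astype(np.int64) + _popcount(az).astype(np.int64)
    return (s % 2) == 0


def noncontextual_clique_partition(S: "PauliSum"):
    """Split terms of S into (symmetry indices, clique index lists) if S is
    noncontextual, else return None.

    Symmetry terms Z' commute with every element of S; the remainder must
    partition into classes with intra-class commutation and inter-class
    anticommutation (transitive commutation on S \\ Z').
    """
    if S.n_terms == 0:
        raise ValueError("empty set")
    C = _pairwise_commute(S.x, S.z)
    sym = np.flatnonzero(C.all(axis=1))
    rest = np.flatnonzero(~C.all(axis=1))
    if len(rest) == 0:
        return sym, []
    Cr = C[np.ix_(rest, rest)]
    # commute-graph must be a disjoint union of cliques
    assigned = np.full(len(rest), -1)
    cliques: list[list[int]] = []
    for i in range(len(rest)):
        if assigned[i] >= 0:
            continue
        members = np.flatnonzero(Cr[i])
        # transitivity: every member must commute with exactly this class
        if not (Cr[members] == Cr[i]).all():
            return None
        if np.any(assigned[members] >= 0):
            return None
        assigned[members] = len(cliques)
        cliques.append([int(rest[m]) for m in members])
    return sym, cliques


def is_noncontextual(S: "PauliSum") -> bool:
    """Commutation restricted to non-symmetry elements is transitive."""
    return noncontextual_clique_partition(S) is not None


# ----------------------------------------------------------------- fixtures

def random_pauli_sum(n_qubits: int, n_terms: int, seed: int,
                     hermitian: bool = True) -> PauliSum:
    """Reproducible random Pauli sum with real (Hermitian) coefficients."""
    rng = np.random.default_rng(seed)
    lim = 1 << n_qubits
    x = rng.integers(0, lim, size=n_terms).astype(np.uint64)
    z = rng.integers(0, lim, size=n_terms).astype(np.uint64)
    c = rng.standard_normal(n_terms).astype(complex)
    if not hermitian:
        c = c + 1j * rng.standard_normal(n_terms)
    return PauliSum(x, z, c, n_qubits)


# ------------------------------------------------------------------ text I/O

def write_pauli_file(path, H: PauliSum, comment: str | None = None) -> None:
    """One term per line: ``<real> <imag> <pauli-string>``; '#' comments."""
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# n_qubits {H.n_qubits}\n")
        for c, s in zip(H.coeffs, H.pauli_strings()):
            fh.write(f"{c.real:+.16e} {c.imag:+.16e} {s}\n")


def read_pauli_file(path) -> PauliSum:
    terms: list[tuple[str, complex]] = []
    n = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "n_qubits":
                    n = int(parts[1])
                continue
            re_, im_, s = line.split()
            terms.append((s, float(re_) + 1j * float(im_)))
            if n is None:
                n = len(s)
    if n is None:
        raise ValueError(f"no Pauli terms found in {path}")
    return PauliSum.from_strings(terms, n_qubits=n)
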