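"""Noncontextual/contextual splitting and contextual-subspace projection.

A set of Pauli terms is noncontextual when commutation restricted to its
non-symmetry elements is transitive: the set splits into a universally
commuting part Z' and cliques C_1..C_m with intra-clique commutation and
inter-clique anticommutation.  Such a Hamiltonian carries a classical
objective over (q, r): q in {+-1}^|G| assigns the independent symmetry
generators G, r is a unit vector of clique-operator expectations, and

    E(q, r) = sum_{B in Z'} h_B <B>_q + sum_i r_i sum_{C in C_i} h_C <B_C>_q

with B_C = C * A_i for clique representatives A_i.  Minimising r in closed
form (negative norm of the clique sums) leaves an exhaustive search over
q, done here for all assignments at once with a fast Walsh-Hadamard
transform.

Enforcing a subset of the noncontextual ground state's stabilizers -
products of the G_j and, after a Givens-rotation sequence mapping
sum_i r_i A_i onto a single Pauli, the clique operator - over the full
Hamiltonian projects it into a contextual subspace on fewer qubits.
Stabilizers are chosen greedily to maximise the l1-norm of a guide
excitation generator (MP2 or CCSD) retained in the subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paulis import (PauliSum, PauliTerm, _I_POWERS, _product_phase,
                     noncontextual_clique_partition)
from .tapering import StabilizerRotations

__all__ = [
    "ContextualSplit", "NoncontextualModel", "StabilizerChoice",
    "ReferenceSector", "reference_perturbative_strategy",
    "select_noncontextual", "solve_noncontextual", "stabilizer_sequence",
    "select_stabilizers", "project_to_subspace", "cs_dd_energy",
]


class ReferenceSector:
    """Reference computational-basis state seen through a tapering.

    Wraps the tapering rotations and the reference occupation bit-mask so
    reduced-frame Pauli operators can be evaluated in the reference state:
    ``value`` returns the +-1 eigenvalue when the back-mapped operator is
    diagonal and 0 when the reference does not fix it.
    """

    def __init__(self, rotations: StabilizerRotations, occupation):
        self.rotations = rotations
        occ = np.asarray(occupation).ravel()
        bits = 0
        for k, o in enumerate(occ):
            if o:
                bits |= 1 << k
        self.occ_bits = bits
        self.n_full = rotations.n_qubits

    def value(self, term: PauliTerm) -> float:
        t = self.rotations.backmap(term)
        if t.x_mask != 0:
            return 0.0
        par = bin(t.z_mask & self.occ_bits).count("1") % 2
        return float(np.sign(t.coefficient.real)) * (1 - 2 * par)


def _commutes_vec(x, z, xs, zs):
    s = (np.bitwise_count(np.uint64(x) & zs).astype(np.int64)
         + np.bitwise_count(np.uint64(z) & xs).astype(np.int64))
    return (s % 2) == 0


# --------------------------------------------------------------- selection

def greedy_noncontextual_indices(H: PauliSum,
                                 order: np.ndarray | None = None) -> np.ndarray:
    """Indices of a noncontextual subset, greedy over a candidate order
    (default: coefficient magnitude, descending).

    Maintains the Z'/clique structure incrementally so each candidate is an
    O(current size) vectorised check rather than a full transitivity test.
    """
    if order is None:
        order = np.argsort(-np.abs(H.coeffs), kind="stable")
    sel_x = np.empty(0, dtype=np.uint64)
    sel_z = np.empty(0, dtype=np.uint64)
    lab = np.empty(0, dtype=np.int64)   # 0 = universal, else clique id
    next_clique = 1
    taken: list[int] = []
    for idx in order:
        x, z = H.x[idx], H.z[idx]
        comm = _commutes_vec(x, z, sel_x, sel_z)
        new_label: int | None = None
        relabel: tuple[np.ndarray, int] | None = None
        if comm.all():
            new_label = 0
        else:
            uni_anti = ~comm & (lab == 0)
            cl_ids = np.unique(lab[lab > 0])
            ok = True
            if uni_anti.any():
                # universal members anticommuting with the candidate must
                # move into the clique structure, which is only consistent
                # with at most one existing clique
                if len(cl_ids) == 0:
                    relabel = (uni_anti, next_clique)
                    new_label = next_clique + 1
                elif len(cl_ids) == 1:
                    members = lab == cl_ids[0]
                    if comm[members].any():
                        ok = False
                    else:
                        relabel = (uni_anti, int(cl_ids[0]))
                        new_label = next_clique
                else:
                    ok = False
            else:
                # candidate must fully commute with at most one clique and
                # fully anticommute with every other
                joined = None
                for c in cl_ids:
                    members = lab == c
                    n_comm = int(comm[members].sum())
                    if n_comm == members.sum():
                        if joined is not None:
                            ok = False
                            break
                        joined = int(c)
                    elif n_comm != 0:
                        ok = False
                        break
                if ok:
                    new_label = joined if joined is not None else next_clique
            if not ok:
                continue
        taken.append(int(idx))
        if relabel is not None:
            lab = lab.copy()
            lab[relabel[0]] = relabel[1]
        lab = np.append(lab, new_label)
        next_clique = int(max(lab.max(initial=0) + 1, next_clique))
        sel_x = np.append(sel_x, x)
        sel_z = np.append(sel_z, z)
    return np.sort(np.array(taken, dtype=np.int64))


@dataclass
class ContextualSplit:
    H_nc: PauliSum
    H_context: PauliSum
    E_nc: float | None = None


def reference_perturbative_strategy(H_full: PauliSum,
                                    reference: ReferenceSector):
    """Noncontextual-selection strategy guided by the reference state.

    All diagonal terms are admitted first (they form the commuting
    backbone); off-diagonal candidates are then offered greedily in order
    of their estimated two-level energy lowering with respect to the
    reference determinant, sqrt(dE^2/4 + h^2) - |dE|/2, where dE is the
    diagonal-energy gap to the determinant the (back-mapped) term excites
    to.  Off resonance this reduces to the perturbative |h|^2/|dE|; at a
    determinant crossing it saturates at |h| instead of diverging.  This
    keeps the cliques that matter energetically - near degeneracy the
    dominant valence pair excitation - rather than whichever term happens
    to carry the largest raw coefficient.
    """
    diag_full = H_full.x == 0
    zd = H_full.z[diag_full]
    cd = H_full.coeffs[diag_full].real
    occ = np.uint64(reference.occ_bits)

    def diag_energy(bits: int) -> float:
        par = (np.bitwise_count(zd & np.uint64(bits)) % 2).astype(np.int64)
        return float((cd * (1 - 2 * par)).sum())

    e_ref = diag_energy(reference.occ_bits)

    def strategy(Ht: PauliSum) -> np.ndarray:
        idx_diag = np.flatnonzero(Ht.x == 0)
        idx_off = np.flatnonzero(Ht.x != 0)
        xf, zf, cbm = reference.rotations.backmap_batch(Ht.x[idx_off],
                                                        Ht.z[idx_off])
        # amplitude of each term between the reference and the determinant
        # it excites to:  P|ref> = c * i^{|x&z|} (-1)^{z.ref} |ref ^ x>
        phase = np.empty(len(idx_off), dtype=complex)
        for k in range(len(idx_off)):
            xz = int(xf[k]) & int(zf[k])
            par = bin(int(zf[k]) & reference.occ_bits).count("1") % 2
            phase[k] = (1j ** (bin(xz).count("1") % 4)) * (1 - 2 * par)
        amps = Ht.coeffs[idx_off] * cbm * phase
        # group terms by the determinant they reach; the group's physical
        # coupling K = |<D|H|ref>| is frame-robust, unlike per-term weights
        groups: dict[int, list[int]] = {}
        for k in range(len(idx_off)):
            groups.setdefault(int(xf[k]), []).append(k)
        scored = []
        for flip, members in groups.items():
            K = abs(sum(amps[k] for k in members))
            dE = diag_energy(reference.occ_bits ^ flip) - e_ref
            # two-level lowering: ~ K^2/dE off resonance, bounded by K at
            # a determinant crossing (no divergence)
            w = np.sqrt(0.25 * dE * dE + K * K) - 0.5 * abs(dE)
            scored.append((w, flip, members))
        scored.sort(key=lambda t: (-t[0], t[1]))
        off_order = []
        for w, flip, members in scored:
            members = sorted(members,
                             key=lambda k: -abs(Ht.coeffs[idx_off[k]]))
            off_order.extend(int(idx_off[k]) for k in members)
        order = np.concatenate([
            idx_diag[np.argsort(-np.abs(Ht.coeffs[idx_diag]), kind="stable")],
            np.array(off_order, dtype=np.int64),
        ])
        return greedy_noncontextual_indices(Ht, order)

    return strategy


def select_noncontextual(H: PauliSum,
                         strategy="greedy_magnitude") -> ContextualSplit:
    """Split H into a noncontextual part and the contextual remainder.

    ``strategy`` is either the name of a built-in rule (currently the
    greedy-by-magnitude default) or a callable ``H -> index array``
    returning the indices of the noncontextual subset.
    """
    if callable(strategy):
        idx = np.asarray(strategy(H), dtype=np.int64)
    elif strategy == "greedy_magnitude":
        idx = greedy_noncontextual_indices(H)
    else:
        raise ValueError(f"unknown selection strategy {strategy!r}")
    mask = np.zeros(H.n_terms, dtype=bool)
    mask[idx] = True
    H_nc = PauliSum(H.x[mask], H.z[mask], H.coeffs[mask], H.n_qubits)
    H_c = PauliSum(H.x[~mask], H.z[~mask], H.coeffs[~mask], H.n_qubits)
    return ContextualSplit(H_nc, H_c)


# ------------------------------------------------------------------- model

@dataclass
class NoncontextualModel:
    n_qubits: int
    generators: list[PauliTerm]          # independent symmetry generators
    q: np.ndarray                        # optimal +-1 assignment
    clique_reps: list[PauliTerm]         # mutually anticommuting, coeff +1
    r: np.ndarray                        # optimal unit vector (may be empty)
    energy: float
    clique_rotations: list[tuple[PauliTerm, float]] = field(
        default_factory=list)
    rotated_rep: PauliTerm | None = None     # image of sum_i r_i A_i
    rotated_rep_sign: float = 1.0

    def rotate(self, S: PauliSum) -> PauliSum:
        """Apply the clique-reduction rotations to an operator."""
        out = S
        for P, th in self.clique_rotations:
            out = out.rotated(P, th)
        return out


def _signed_basis(terms: list[PauliTerm], n_qubits: int):
    """Sign-tracked GF(2) basis over mutually commuting +1 Paulis.

    Returns (generators, decomposition) with decomposition[i] =
    (sign_i, exponent mask) such that term_i = sign_i * prod_j gens[j]^e_ij
    as an exact operator identity.
    """
    gens: list[PauliTerm] = []
    rows: list[tuple[int, PauliTerm, int]] = []   # (pivot, generator, emask)
    deco: list[tuple[float, int]] = []

    def vec(t: PauliTerm) -> int:
        return (t.x_mask << n_qubits) | t.z_mask

    for t in terms:
        acc = PauliTerm(1.0, 0, 0, n_qubits)
        emask = 0
        for pivot, red, rexp in rows:
            if ((vec(t) ^ vec(acc)) >> pivot) & 1:
                acc = acc.multiply(red)
                emask ^= rexp
        residual = vec(t) ^ vec(acc)
        prod = acc.multiply(PauliTerm(1.0, t.x_mask, t.z_mask, n_qubits))
        sign = prod.coefficient
        if abs(sign.imag) > 1e-10:
            raise AssertionError("noncontextual symmetry group is not abelian")
        if residual == 0:
            deco.append((float(np.sign(sign.real)), emask))
        else:
            gen = PauliTerm(1.0, prod.x_mask, prod.z_mask, n_qubits)
            gi = len(gens)
            gens.append(gen)
            rows.append((residual.bit_length() - 1, gen, 1 << gi))
            rows.sort(key=lambda rr: -rr[0])
            deco.append((float(np.sign(sign.real)), emask ^ (1 << gi)))
    return gens, deco


def _walsh_hadamard(a: np.ndarray) -> np.ndarray:
    """out[q] = sum_e a[e] * (-1)^{popcount(e & q)} (fast transform)."""
    a = a.copy()
    h = 1
    n = len(a)
    while h < n:
        a = a.reshape(-1, 2 * h)
        left = a[:, :h].copy()
        right = a[:, h:].copy()
        a[:, :h] = left + right
        a[:, h:] = left - right
        a = a.reshape(-1)
        h *= 2
    return a


def solve_noncontextual(split: ContextualSplit,
                        reference: ReferenceSector | None = None,
                        q_search_limit: int = 20,
                        seed: int = 0) -> tuple[float, NoncontextualModel]:
    """Minimise the classical objective of the noncontextual part.

    r is optimal in closed form (negative norm of the clique sums); q is
    searched exhaustively via the Walsh-Hadamard transform, with a seeded
    annealing fallback beyond ``q_search_limit`` free generators.

    With a ``reference`` sector, symmetry-generator assignments that the
    reference state determines are clamped to it and only the remaining
    directions are searched.  This keeps the noncontextual state in the
    reference's charge/spin sector; the unconstrained minimum of the
    classical objective generally lies in an unphysical sector of the
    tapered register.
    """
    H_nc = split.H_nc
    n = H_nc.n_qubits
    part = noncontextual_clique_partition(H_nc)
    if part is None:
        raise ValueError("H_nc is not noncontextual")
    sym_idx, cliques = part
    terms = H_nc.terms()
    reps = []
    for cl in cliques:
        rep_i = max(cl, key=lambda i: abs(terms[i].coefficient))
        t = terms[rep_i]
        reps.append(PauliTerm(1.0, t.x_mask, t.z_mask, n))
    basis_inputs: list[PauliTerm] = []
    sources: list[tuple[float, int]] = []   # (signed coeff, clique idx|-1)
    for i in sym_idx:
        t = terms[i]
        basis_inputs.append(PauliTerm(1.0, t.x_mask, t.z_mask, n))
        sources.append((t.coefficient.real, -1))
    for ci, cl in enumerate(cliques):
        A = reps[ci]
        for i in cl:
            t = terms[i]
            B = PauliTerm(1.0, t.x_mask, t.z_mask, n).multiply(A)
            basis_inputs.append(PauliTerm(1.0, B.x_mask, B.z_mask, n))
            sources.append((t.coefficient.real * B.coefficient.real, ci))
    gens, deco = _signed_basis(basis_inputs, n)
    k = len(gens)
    clamped: dict[int, float] = {}
    if reference is not None:
        for i, g in enumerate(gens):
            v = reference.value(g)
            if v != 0.0:
                clamped[i] = v
    free = [i for i in range(k) if i not in clamped]
    if len(free) > q_search_limit:
        return _solve_annealed(split, gens, deco, sources, reps, seed,
                               clamped, free)
    dim = 1 << len(free)
    sym_vec = np.zeros(dim)
    cl_vecs = np.zeros((len(reps), dim))
    for (coeff, ci), (sgn, emask) in zip(sources, deco):
        val = coeff * sgn
        fe = 0
        for bi, i in enumerate(free):
            if (emask >> i) & 1:
                fe |= 1 << bi
        for i, cv in clamped.items():
            if (emask >> i) & 1:
                val *= cv
        if ci < 0:
            sym_vec[fe] += val
        else:
            cl_vecs[ci, fe] += val
    sym_q = _walsh_hadamard(sym_vec)
    if len(reps):
        cl_q = np.vstack([_walsh_hadamard(v) for v in cl_vecs])
        total = sym_q - np.sqrt((cl_q ** 2).sum(axis=0))
    else:
        total = sym_q
    best = int(np.argmin(total))
    e0 = float(total[best])
    q = np.zeros(k)
    for i, cv in clamped.items():
        q[i] = cv
    for bi, i in enumerate(free):
        q[i] = 1 - 2 * ((best >> bi) & 1)
    if len(reps):
        a = cl_q[:, best]
        nrm = np.linalg.norm(a)
        r = -a / nrm if nrm > 1e-14 else -np.eye(len(reps))[0]
    else:
        r = np.zeros(0)
    model = NoncontextualModel(n, gens, q, reps, r, e0)
    _attach_clique_rotations(model)
    split.E_nc = e0
    return e0, model


def _solve_annealed(split, gens, deco, sources, reps, seed, clamped,
                    free):  # pragma: no cover - fallback for huge models
    rng = np.random.default_rng(seed)
    n = split.H_nc.n_qubits
    k = len(gens)

    def energy(free_bits):
        sym = 0.0
        a = np.zeros(len(reps))
        for (coeff, ci), (sgn, emask) in zip(sources, deco):
            val = coeff * sgn
            for bi, i in enumerate(free):
                if (emask >> i) & 1 and (free_bits >> bi) & 1:
                    val = -val
            for i, cv in clamped.items():
                if (emask >> i) & 1:
                    val *= cv
            if ci < 0:
                sym += val
            else:
                a[ci] += val
        return sym - np.linalg.norm(a), a

    bits = 0
    e, _ = energy(bits)
    best_bits, best_e = bits, e
    T = 1.0
    for _ in range(20000):
        j = int(rng.integers(len(free)))
        cand = bits ^ (1 << j)
        ec, _ = energy(cand)
        if ec < e or rng.random() < np.exp(-(ec - e) / max(T, 1e-9)):
            bits, e = cand, ec
            if e < best_e:
                best_bits, best_e = bits, e
        T *= 0.9995
    e0, a = energy(best_bits)
    e0 = float(e0)
    q = np.zeros(k)
    for i, cv in clamped.items():
        q[i] = cv
    for bi, i in enumerate(free):
        q[i] = 1 - 2 * ((best_bits >> bi) & 1)
    nrm = np.linalg.norm(a)
    r = -a / nrm if nrm > 1e-14 else np.zeros(len(reps))
    model = NoncontextualModel(n, gens, q, reps, r, e0)
    _attach_clique_rotations(model)
    split.E_nc = e0
    return e0, model


def _attach_clique_rotations(model: NoncontextualModel) -> None:
    """Givens-rotation sequence mapping sum_i r_i A_i onto +-A_1."""
    reps, r = model.clique_reps, model.r
    model.clique_rotations = []
    if len(reps) == 0:
        model.rotated_rep = None
        return
    if len(reps) == 1:
        model.rotated_rep = reps[0]
        model.rotated_rep_sign = float(np.sign(r[0])) if len(r) else 1.0
        return
    v = np.array(r, dtype=float)
    rots = []
    for j in range(1, len(reps)):
        if abs(v[j]) < 1e-14:
            continue
        theta = np.arctan2(v[j], v[0])
        prod = reps[0].multiply(reps[j])
        coeff = 1j * prod.coefficient      # i A_1 A_j is a Hermitian Pauli
        if abs(coeff.imag) > 1e-10:
            raise AssertionError("clique rotation generator is not Hermitian")
        P = PauliTerm(1.0, prod.x_mask, prod.z_mask, model.n_qubits)
        rots.append((P, -float(np.sign(coeff.real)) * theta))
        v[0] = np.hypot(v[0], v[j])
        v[j] = 0.0
    model.clique_rotations = rots
    model.rotated_rep = reps[0]
    model.rotated_rep_sign = float(np.sign(v[0]))


# ------------------------------------------------------- stabilizer choice

@dataclass
class StabilizerChoice:
    stabilizers: list[PauliTerm]     # in the clique-rotated frame, coeff +1
    eigenvalues: list[float]
    target_qubits: int
    score: float
    includes_clique_rep: bool = False


def _pool(model: NoncontextualModel):
    """Every product of the symmetry generators (and the rotated clique
    representative) with its fixed eigenvalue; excludes the identity."""
    xs = np.array([0], dtype=np.uint64)
    zs = np.array([0], dtype=np.uint64)
    vals = np.array([1.0])
    phases = np.array([1.0 + 0j])
    members = list(model.generators)
    mvals = [float(v) for v in model.q]
    if model.rotated_rep is not None:
        members.append(model.rotated_rep)
        mvals.append(model.rotated_rep_sign)
    for g, qv in zip(members, mvals):
        ph = _I_POWERS[_product_phase(
            xs, zs, np.full_like(xs, np.uint64(g.x_mask)),
            np.full_like(zs, np.uint64(g.z_mask)))]
        xs = np.concatenate([xs, xs ^ np.uint64(g.x_mask)])
        zs = np.concatenate([zs, zs ^ np.uint64(g.z_mask)])
        phases = np.concatenate([phases, phases * ph])
        vals = np.concatenate([vals, vals * qv])
    if np.abs(phases.imag).max(initial=0) > 1e-10:
        raise AssertionError("stabilizer pool acquired complex phases")
    vals = vals * phases.real
    n_gen_only = 1 << len(model.generators)
    uses_rep = np.arange(len(xs)) >= n_gen_only
    return xs[1:], zs[1:], vals[1:], uses_rep[1:]


def _comm_matrix(px, pz, gx, gz, chunk: int = 4096) -> np.ndarray:
    """Boolean commutation table (pool x guide terms)."""
    out = np.empty((len(px), len(gx)), dtype=bool)
    for k0 in range(0, len(px), chunk):
        k1 = min(k0 + chunk, len(px))
        s = (np.bitwise_count(px[k0:k1, None] & gz[None, :]).astype(np.int64)
             + np.bitwise_count(pz[k0:k1, None] & gx[None, :]).astype(np.int64))
        out[k0:k1] = (s % 2) == 0
    return out


def _comm_rows(px, pz, gx, gz, rows):
    s = (np.bitwise_count(px[rows][:, None] & gz[None, :]).astype(np.int64)
         + np.bitwise_count(pz[rows][:, None] & gx[None, :]).astype(np.int64))
    return (s % 2) == 0


def stabilizer_sequence(model: NoncontextualModel, guide: PauliSum,
                        hamiltonian: PauliSum | None = None,
                        tie_tol: float = 0.01):
    """Nested greedy stabilizer ordering for all subspace sizes at once.

    Returns (stabilizers, eigenvalues, scores, uses_rep): position k holds
    the k-th chosen stabilizer; enforcing the first k gives the
    (n_qubits - k)-qubit subspace, and scores[k] is the retained guide
    l1-norm after k choices (scores[0] is the full guide norm).  The guide
    (and ``hamiltonian``, if given) must already be in the clique-rotated
    frame.

    The primary criterion is the retained guide l1-norm; candidates within
    ``tie_tol`` (relative) of the best are near-ties and, when
    ``hamiltonian`` is supplied, are re-ranked by the Hamiltonian l1-norm
    they retain.  A guide without singles amplitudes is otherwise blind to
    stabilizers that destroy the singles sector of the Hamiltonian.
    Remaining exact ties break lexicographically on the Pauli string.
    """
    n = model.n_qubits
    px, pz, pvals, prep = _pool(model)
    gw = np.abs(guide.coeffs)
    C = _comm_matrix(px, pz, guide.x, guide.z)
    hx = hz = hw = None
    keep_h = None
    if hamiltonian is not None:
        hx, hz = hamiltonian.x, hamiltonian.z
        hw = np.abs(hamiltonian.coeffs)
        keep_h = np.ones(len(hw), dtype=bool)
    chosen: list[int] = []
    basis: list[int] = []        # pivot-reduced span of chosen stabilizers
    keep = np.ones(len(gw), dtype=bool)
    scores = [float(gw.sum())]
    rank_total = _gf2_rank([(int(x) << n) | int(z) for x, z in zip(px, pz)])

    def lex_key(i):
        return PauliTerm(1.0, int(px[i]), int(pz[i]), n).pauli_string()

    for _ in range(min(n, rank_total)):
        sc = C[:, keep] @ gw[keep]
        best_sc = sc.max()
        cand = np.flatnonzero(sc >= best_sc * (1.0 - tie_tol) - 1e-12)
        if hamiltonian is not None and len(cand) > 1:
            Ch = _comm_rows(px, pz, hx[keep_h], hz[keep_h], cand)
            sh = Ch @ hw[keep_h]
            ranked = sorted(range(len(cand)),
                            key=lambda j: (-sh[j], -sc[cand[j]],
                                           lex_key(cand[j])))
            order = [int(cand[j]) for j in ranked]
        else:
            order = [int(i) for i in
                     sorted(cand, key=lambda i: (-sc[i], lex_key(i)))]
        pick = None
        for i in order:
            if _gf2_reduce((int(px[i]) << n) | int(pz[i]), basis) != 0:
                pick = i
                break
        if pick is None:
            # all near-optimal candidates dependent; fall back globally
            for i in np.argsort(-sc, kind="stable"):
                if _gf2_reduce((int(px[i]) << n) | int(pz[i]), basis) != 0:
                    pick = int(i)
                    break
        if pick is None:
            break
        chosen.append(pick)
        basis.append(_gf2_reduce((int(px[pick]) << n) | int(pz[pick]), basis))
        basis.sort(reverse=True)
        keep &= C[pick]
        if hamiltonian is not None:
            s2 = (np.bitwise_count(px[pick] & hz).astype(np.int64)
                  + np.bitwise_count(pz[pick] & hx).astype(np.int64))
            keep_h &= (s2 % 2) == 0
        scores.append(float(gw[keep].sum()))
    stabs = [PauliTerm(1.0, int(px[i]), int(pz[i]), n) for i in chosen]
    eigs = [float(pvals[i]) for i in chosen]
    uses = [bool(prep[i]) for i in chosen]
    return stabs, eigs, scores, uses


def _gf2_reduce(v: int, basis: list[int]) -> int:
    """Reduce v against a basis sorted descending with unique leading bits."""
    for w in basis:
        if v == 0:
            break
        if (v ^ w) < v:
            v ^= w
    return v


def _gf2_rank(vecs: list[int]) -> int:
    basis: list[int] = []
    for v in vecs:
        v = _gf2_reduce(v, basis)
        if v:
            basis.append(v)
            basis.sort(reverse=True)
    return len(basis)


def select_stabilizers(model: NoncontextualModel, n_q: int,
                       guide: PauliSum,
                       hamiltonian: PauliSum | None = None,
                       tie_tol: float = 0.01) -> StabilizerChoice:
    """Greedy choice of (n_qubits - n_q) stabilizers for one subspace size.

    Wraps :func:`stabilizer_sequence`; sweeping n_q reuses prefixes of the
    same nested ordering, so the retained score is monotone in n_q.
    """
    n = model.n_qubits
    n_fix = n - n_q
    if n_q < 0 or n_fix < 0:
        raise ValueError(f"n_q must lie in [0, {n}]")
    stabs, eigs, scores, uses = stabilizer_sequence(model, guide,
                                                    hamiltonian, tie_tol)
    if n_fix > len(stabs):
        raise ValueError(
            f"noncontextual model only supports {len(stabs)} independent "
            f"stabilizers; cannot project to {n_q} qubits")
    return StabilizerChoice(stabs[:n_fix], eigs[:n_fix], n_q,
                            scores[n_fix], any(uses[:n_fix]))


# -------------------------------------------------------------- projection

def project_to_subspace(H: PauliSum, choice: StabilizerChoice,
                        model: NoncontextualModel) -> PauliSum:
    """Project H onto the chosen stabilizers' fixed-eigenvalue subspace.

    H is first taken to the clique-rotated frame; terms failing to commute
    with an enforced stabilizer are dropped (the contextual approximation),
    the rest have the stabilizer eigenvalues substituted, and the fixed
    qubits are removed.
    """
    if not choice.stabilizers:
        return H.copy()
    H_rot = model.rotate(H)
    rots = StabilizerRotations(choice.stabilizers, H.n_qubits)
    return rots.project(H_rot, choice.eigenvalues, drop_noncommuting=True)


def cs_dd_energy(H_reduced: PauliSum) -> float:
    """Exact lowest eigenvalue of the reduced Hamiltonian (CS-DD)."""
    if H_reduced.n_qubits == 0 or H_reduced.n_terms == 0:
        return float(H_reduced.identity_coefficient().real)
    return H_reduced.ground_energy_exact()
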