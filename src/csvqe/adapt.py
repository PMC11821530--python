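"""Adaptive ansatz construction with optional hardware awareness.

qubit-ADAPT grows the ansatz one Pauli rotation exp(i theta P) at a time:
each cycle scores every pool operator by the energy gradient at zero,

    f(P) = d/dtheta < e^{-i theta P} H e^{i theta P} > |_0 = i <[H, P]>,

appends the best-scoring operator and re-optimises all parameters by BFGS.
The pool is the set of individual Pauli strings of the (projected) UCCSD
excitation generator.  Hardware awareness multiplies |f(P)| by a biasing
factor in [0, 1] derived from how close the prospective circuit's coupling
graph is to a subgraph of the target device topology: delete up to D nodes
(cheapest first, by the summed weight s(n) of their incident edges) until
the remainder embeds (VF2), then score (1 - s(n)/W)^b; no embedding within
depth D scores zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import scipy.optimize as sopt

from .circuits import CircuitIR, circuit_graph, compile_exponential
from .paulis import PauliSum, PauliTerm

__all__ = ["BiasConfig", "AdaptResult", "pauli_pool", "pool_gradient",
           "bias_factor", "adapt_run"]


@dataclass
class BiasConfig:
    max_depth: int = 2       # D: maximum number of deleted nodes
    strength: float = 1.0    # b > 0: penalty exponent

    def __post_init__(self):
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0")
        if self.strength <= 0:
            raise ValueError("strength must be > 0")


def pauli_pool(generator: PauliSum, tol: float = 1e-8) -> list[PauliTerm]:
    """Individual Pauli strings of an anti-Hermitian excitation generator.

    Each distinct string becomes one pool element (coefficient stripped);
    strings that projected to the identity are dropped.  Deterministic
    order: descending |coefficient|, then lexicographic.
    """
    items = [(abs(t.coefficient), t) for t in generator
             if not t.is_identity and abs(t.coefficient) > tol]
    items.sort(key=lambda it: (-it[0], it[1].pauli_string()))
    seen = set()
    pool = []
    for _, t in items:
        key = (t.x_mask, t.z_mask)
        if key not in seen:
            seen.add(key)
            pool.append(PauliTerm(1.0, t.x_mask, t.z_mask, t.n_qubits))
    if not pool:
        raise ValueError("empty operator pool")
    return pool


def _apply_term(t: PauliTerm, v: np.ndarray, n: int) -> np.ndarray:
    return t.to_sum().apply_to_statevector(v)


def pool_gradient(H: PauliSum, psi: np.ndarray, P: PauliTerm) -> float:
    """i <[H, P]> = -2 Im <psi| H P |psi> at theta = 0."""
    if (1 << H.n_qubits) != psi.shape[0] or P.n_qubits != H.n_qubits:
        raise ValueError("dimension mismatch")
    Pv = _apply_term(P, psi, H.n_qubits)
    HPv = H.apply_to_statevector(Pv)
    return float(-2.0 * np.imag(np.vdot(psi, HPv)))


def bias_factor(gc: nx.Graph, gt: nx.Graph, cfg: BiasConfig) -> float:
    """Hardware-aware biasing factor in [0, 1] (Algorithm-2 style search).

    Node subsets of each size are tried in ascending incident-edge weight
    s(n); the first depth admitting a subgraph embedding of the remainder
    into the target wins, scoring (1 - s(n)/W)^b.
    """
    if gt.number_of_nodes() == 0:
        raise ValueError("empty target graph")
    W = sum(d.get("weight", 1.0) for _, _, d in gc.edges(data=True))
    nodes = sorted(gc.nodes())
    for d in range(cfg.max_depth + 1):
        subsets = []
        for sub in combinations(nodes, d):
            s = sum(dd.get("weight", 1.0)
                    for u, v, dd in gc.edges(data=True)
                    if u in sub or v in sub)
            subsets.append((s, sub))
        subsets.sort(key=lambda t: (t[0], t[1]))
        for s, sub in subsets:
            rem = gc.copy()
            rem.remove_nodes_from(sub)
            rem.remove_nodes_from(list(nx.isolates(rem)))
            if rem.number_of_edges() == 0:
                ok = True
            else:
                gm = nx.isomorphism.GraphMatcher(gt, rem)
                ok = gm.subgraph_is_monomorphic()
            if ok:
                if W == 0:
                    return 1.0
                return float((1.0 - s / W) ** cfg.strength)
    return 0.0


@dataclass
class AdaptResult:
    circuit: CircuitIR
    parameters: dict[str, float]
    energy: float
    energy_trace: list[float]
    gradient_l1_trace: list[float]
    operators: list[PauliTerm]
    converged: bool = True


def _energy_fn(H: PauliSum, circuit: CircuitIR, names: list[str],
               initial: np.ndarray):
    mat = H.to_sparse_matrix() if H.n_qubits <= 13 else None
    op = H if mat is None else None

    def energy(x: np.ndarray) -> float:
        vals = dict(zip(names, x))
        v = circuit.statevector(vals, initial=initial)
        if mat is not None:
            return float(np.real(np.vdot(v, mat @ v)))
        return op.expectation(v)

    return energy


def _parameter_shift_grad(energy, x):
    g = np.zeros_like(x)
    for k in range(len(x)):
        xp = x.copy()
        xp[k] += np.pi / 4
        xm = x.copy()
        xm[k] -= np.pi / 4
        g[k] = energy(xp) - energy(xm)
    return g


def adapt_run(H: PauliSum, pool: list[PauliTerm],
              target_graph: nx.Graph | None = None,
              cfg: BiasConfig | None = None,
              initial_state: np.ndarray | int = 0,
              max_cycles: int = 50, grad_l1_tol: float = 1e-3,
              seed: int = 0, bfgs_gtol: float = 1e-6,
              stop_energy: float | None = None) -> AdaptResult:
    """Adaptive ansatz growth (standard qubit-ADAPT when no target graph).

    Scoring uses |f(P)|, multiplied by the hardware bias factor when a
    target topology is given; ties break by smaller compiled two-qubit
    count, then lexicographic Pauli string.  On an all-zero-gradient
    plateau the parameters are perturbed once (seeded, 1e-3) and rescored
    before declaring convergence.
    """
    cfg = cfg or BiasConfig()
    n = H.n_qubits
    rng = np.random.default_rng(seed)
    dim = 1 << n
    if isinstance(initial_state, (int, np.integer)):
        init = np.zeros(dim, dtype=complex)
        init[int(initial_state)] = 1.0
    else:
        init = np.asarray(initial_state, dtype=complex)
        init = init / np.linalg.norm(init)
    circuit = CircuitIR(n)
    names: list[str] = []
    chosen: list[PauliTerm] = []
    x = np.zeros(0)
    energy = _energy_fn(H, circuit, names, init)
    e = energy(x)
    trace = [e]
    grad_trace: list[float] = []
    perturbed = False
    for cycle in range(max_cycles):
        vals = dict(zip(names, x))
        psi = circuit.statevector(vals, initial=init)
        grads = np.array([pool_gradient(H, psi, P) for P in pool])
        l1 = float(np.abs(grads).sum())
        grad_trace.append(l1)
        if l1 < grad_l1_tol:
            if not perturbed and len(x):
                # one seeded perturbation to escape a symmetric plateau
                x = x + 1e-3 * rng.standard_normal(len(x))
                perturbed = True
                vals = dict(zip(names, x))
                psi = circuit.statevector(vals, initial=init)
                grads = np.array([pool_gradient(H, psi, P) for P in pool])
                l1 = float(np.abs(grads).sum())
                if l1 < grad_l1_tol:
                    break
            else:
                break
        scores = np.abs(grads)
        if target_graph is not None:
            base = circuit_graph(circuit)
            biases = []
            for P in pool:
                trial = circuit.copy()
                trial.extend(compile_exponential(P, 0.0))
                biases.append(bias_factor(circuit_graph(trial), target_graph,
                                          cfg))
            biases = np.array(biases)
            if np.any((biases > 0) & (scores > 0)):
                scores = scores * biases
        order = sorted(
            range(len(pool)),
            key=lambda i: (-scores[i],
                           compile_exponential(pool[i], 0.0).two_qubit_count(),
                           pool[i].pauli_string()))
        best = order[0]
        if scores[best] <= 0:
            break
        name = f"t{len(names)}"
        circuit.extend(compile_exponential(pool[best], name))
        names.append(name)
        chosen.append(pool[best])
        x = np.concatenate([x, [0.0]])
        energy = _energy_fn(H, circuit, names, init)
        res = sopt.minimize(energy, x, jac=lambda xx: _parameter_shift_grad(
            energy, xx), method="BFGS",
            options={"gtol": bfgs_gtol, "maxiter": 200})
        x = res.x
        e = float(res.fun)
        trace.append(e)
        if stop_energy is not None and e <= stop_energy:
            break
    return AdaptResult(circuit, dict(zip(names, x)), e, trace, grad_trace,
                       chosen, converged=True)
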