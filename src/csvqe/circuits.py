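"""Gate-level circuit representation, statevector simulation and routing.

Circuits are ordered gate lists over a small native set (H, X, Rx, Ry, Rz,
CNOT, CPhase).  Rotation angles may be bound numbers or named parameters
resolved at simulation time.  The computational-basis convention matches
the Pauli layer: qubit 0 is the most significant index bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .paulis import PauliTerm

__all__ = ["Gate", "CircuitIR", "compile_exponential", "circuit_graph",
           "route_and_count", "ring_subgraph", "ring_graph", "line_graph",
           "heavy_hex_falcon", "heavy_hex_lattice", "read_edge_list",
           "write_edge_list"]

_ONE_QUBIT = {"H", "X", "Rx", "Ry", "Rz"}
_TWO_QUBIT = {"CNOT", "CPhase"}
_PARAMETRIC = {"Rx", "Ry", "Rz", "CPhase"}


@dataclass(frozen=True)
class Gate:
    name: str
    qubits: tuple[int, ...]
    #: bound angle (float), parameter name (str), scaled parameter
    #: ((name, scale) tuple), or None for non-parametric gates
    param: float | str | tuple[str, float] | None = None

    def bound(self, values: dict[str, float]) -> float:
        if self.param is None:
            return 0.0
        if isinstance(self.param, str):
            return float(values[self.param])
        if isinstance(self.param, tuple):
            name, scale = self.param
            return float(values[name]) * scale
        return float(self.param)

    def parameter_name(self) -> str | None:
        if isinstance(self.param, str):
            return self.param
        if isinstance(self.param, tuple):
            return self.param[0]
        return None


@dataclass
class CircuitIR:
    n_qubits: int
    gates: list[Gate] = field(default_factory=list)

    # ----------------------------------------------------------- building
    def add(self, name: str, qubits, param=None) -> "CircuitIR":
        qubits = tuple(int(q) for q in (qubits if np.iterable(qubits)
                                        else (qubits,)))
        if name not in _ONE_QUBIT | _TWO_QUBIT:
            raise ValueError(f"unknown gate {name!r}")
        if any(q >= self.n_qubits or q < 0 for q in qubits):
            raise ValueError("qubit index out of range")
        if name in _PARAMETRIC and param is None:
            raise ValueError(f"{name} requires an angle")
        self.gates.append(Gate(name, qubits, param))
        return self

    def extend(self, other: "CircuitIR") -> "CircuitIR":
        if other.n_qubits != self.n_qubits:
            raise ValueError("qubit-count mismatch")
        self.gates.extend(other.gates)
        return self

    def parameters(self) -> list[str]:
        seen: list[str] = []
        for g in self.gates:
            name = g.parameter_name()
            if name is not None and name not in seen:
                seen.append(name)
        return seen

    def two_qubit_count(self) -> int:
        return sum(1 for g in self.gates if g.name in _TWO_QUBIT)

    def cnot_count(self) -> int:
        return sum(1 for g in self.gates if g.name == "CNOT")

    def copy(self) -> "CircuitIR":
        return CircuitIR(self.n_qubits, list(self.gates))

    # --------------------------------------------------------- simulation
    def statevector(self, values: dict[str, float] | None = None,
                    initial: np.ndarray | int = 0) -> np.ndarray:
        """Apply the circuit to ``initial`` (basis index or vector)."""
        values = values or {}
        dim = 1 << self.n_qubits
        if isinstance(initial, (int, np.integer)):
            v = np.zeros(dim, dtype=complex)
            v[int(initial)] = 1.0
        else:
            v = np.asarray(initial, dtype=complex).copy()
            if v.shape[0] != dim:
                raise ValueError("initial state dimension mismatch")
        t = v.reshape((2,) * self.n_qubits)
        for g in self.gates:
            t = _apply_gate(t, g, g.bound(values), self.n_qubits)
        return t.reshape(dim)

    def unitary(self, values: dict[str, float] | None = None) -> np.ndarray:
        dim = 1 << self.n_qubits
        cols = [self.statevector(values, b) for b in range(dim)]
        return np.column_stack(cols)

    def to_qasm(self, values: dict[str, float] | None = None) -> str:
        """OpenQASM 2.0 export (parameters must be bound)."""
        values = values or {}
        lines = ["OPENQASM 2.0;", 'include "qelib1.inc";',
                 f"qreg q[{self.n_qubits}];"]
        for g in self.gates:
            th = g.bound(values)
            if g.name == "H":
                lines.append(f"h q[{g.qubits[0]}];")
            elif g.name == "X":
                lines.append(f"x q[{g.qubits[0]}];")
            elif g.name in ("Rx", "Ry", "Rz"):
                lines.append(f"{g.name.lower()}({th}) q[{g.qubits[0]}];")
            elif g.name == "CNOT":
                lines.append(f"cx q[{g.qubits[0]}],q[{g.qubits[1]}];")
            elif g.name == "CPhase":
                lines.append(f"cu1({th}) q[{g.qubits[0]}],q[{g.qubits[1]}];")
        return "\n".join(lines) + "\n"


def _gate_matrix(name: str, theta: float) -> np.ndarray:
    if name == "H":
        return np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)
    if name == "X":
        return np.array([[0, 1], [1, 0]], dtype=complex)
    if name == "Rx":
        c, s = np.cos(theta / 2), np.sin(theta / 2)
        return np.array([[c, -1j * s], [-1j * s, c]])
    if name == "Ry":
        c, s = np.cos(theta / 2), np.sin(theta / 2)
        return np.array([[c, -s], [s, c]], dtype=complex)
    if name == "Rz":
        return np.diag([np.exp(-1j * theta / 2), np.exp(1j * theta / 2)])
    if name == "CNOT":
        return np.array([[1, 0, 0, 0], [0, 1, 0, 0],
                         [0, 0, 0, 1], [0, 0, 1, 0]], dtype=complex)
    if name == "CPhase":
        return np.diag([1, 1, 1, np.exp(1j * theta)]).astype(complex)
    raise ValueError(name)


def _apply_gate(t: np.ndarray, g: Gate, theta: float, n: int) -> np.ndarray:
    U = _gate_matrix(g.name, theta)
    k = len(g.qubits)
    t = np.moveaxis(t, list(g.qubits), range(k))
    rest = t.shape[k:]
    t = t.reshape(1 << k, -1)
    t = U @ t
    t = t.reshape((2,) * k + rest)
    return np.moveaxis(t, range(k), list(g.qubits))


# ------------------------------------------------------ Pauli exponentials

def compile_exponential(P: PauliTerm, theta: float | str) -> CircuitIR:
    """Circuit for exp(i theta P) for a single Pauli string.

    Standard construction: single-qubit basis changes onto Z, a CNOT
    parity ladder onto the last support qubit, Rz(-2 theta) there, then
    the inverse ladder and basis changes.  Exact (no global phase) for
    any Pauli string; ``theta`` may be a parameter name, in which case the
    Rz angle resolves to -2*theta via an internal wrapper gate.
    """
    n = P.n_qubits
    c = CircuitIR(n)
    support = [k for k in range(n)
               if (P.x_mask >> k) & 1 or (P.z_mask >> k) & 1]
    if not support:
        raise ValueError("identity Pauli has no circuit realisation")
    pre: list[Gate] = []
    post: list[Gate] = []
    for q in support:
        xb = (P.x_mask >> q) & 1
        zb = (P.z_mask >> q) & 1
        if xb and not zb:        # X -> Z
            pre.append(Gate("H", (q,)))
            post.append(Gate("H", (q,)))
        elif xb and zb:          # Y -> Z
            pre.append(Gate("Rx", (q,), np.pi / 2))
            post.append(Gate("Rx", (q,), -np.pi / 2))
    target = support[-1]
    ladder = [Gate("CNOT", (q, target)) for q in support[:-1]]
    c.gates.extend(pre)
    c.gates.extend(ladder)
    if isinstance(theta, str):
        c.gates.append(Gate("Rz", (target,), (theta, -2.0)))
    else:
        c.gates.append(Gate("Rz", (target,), -2.0 * float(theta)))
    c.gates.extend(reversed(ladder))
    c.gates.extend(reversed(post))
    return c


# ------------------------------------------------------------------ graphs

def circuit_graph(c: CircuitIR) -> nx.Graph:
    """Weighted coupling graph: edge weight = number of two-qubit gates."""
    G = nx.Graph()
    for g in c.gates:
        if g.name in _TWO_QUBIT:
            u, v = g.qubits
            if G.has_edge(u, v):
                G[u][v]["weight"] += 1.0
            else:
                G.add_edge(u, v, weight=1.0)
        else:
            G.add_node(g.qubits[0])
    return G


def ring_graph(n: int) -> nx.Graph:
    G = nx.cycle_graph(n)
    nx.set_edge_attributes(G, 1.0, "weight")
    return G


def line_graph(n: int) -> nx.Graph:
    G = nx.path_graph(n)
    nx.set_edge_attributes(G, 1.0, "weight")
    return G


#: 27-qubit heavy-hex coupling of the IBM Falcon generation
_FALCON27_EDGES = [
    (0, 1), (1, 2), (1, 4), (2, 3), (3, 5), (4, 7), (5, 8), (6, 7),
    (7, 10), (8, 9), (8, 11), (10, 12), (11, 14), (12, 13), (12, 15),
    (13, 14), (14, 16), (15, 18), (16, 19), (17, 18), (18, 21), (19, 20),
    (19, 22), (21, 23), (22, 25), (23, 24), (24, 25), (25, 26),
]


def heavy_hex_falcon() -> nx.Graph:
    """The 27-qubit heavy-hex device topology (Falcon series)."""
    G = nx.Graph()
    G.add_nodes_from(range(27))
    G.add_edges_from(_FALCON27_EDGES)
    nx.set_edge_attributes(G, 1.0, "weight")
    return G


def heavy_hex_lattice(rows: int, cols: int) -> nx.Graph:
    """Heavy-hex lattice: hexagonal lattice with an extra qubit on every
    edge; rows x cols hexagon cells.  rows=3, cols=5 has 127 qubits
    matching the Eagle-generation footprint."""
    hexa = nx.hexagonal_lattice_graph(rows, cols)
    G = nx.Graph()
    mapping = {v: i for i, v in enumerate(sorted(hexa.nodes()))}
    nxt = len(mapping)
    for u, v in sorted(hexa.edges()):
        mid = nxt
        nxt += 1
        G.add_edge(mapping[u], mid, weight=1.0)
        G.add_edge(mid, mapping[v], weight=1.0)
    return G


def ring_subgraph(n: int, device: nx.Graph):
    """Nodes of an n-cycle embedded in the device graph, or None."""
    cyc = nx.cycle_graph(n)
    gm = nx.isomorphism.GraphMatcher(device, cyc)
    for mapping in gm.subgraph_monomorphisms_iter():
        inv = {v: k for k, v in mapping.items()}
        return [inv[i] for i in range(n)]
    return None


def read_edge_list(path) -> nx.Graph:
    """Weighted edge list: lines of ``u v weight`` ('#' comments)."""
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            u, v = int(parts[0]), int(parts[1])
            w = float(parts[2]) if len(parts) > 2 else 1.0
            G.add_edge(u, v, weight=w)
    return G


def write_edge_list(path, G: nx.Graph) -> None:
    with open(path, "w") as fh:
        for u, v, d in G.edges(data=True):
            fh.write(f"{u} {v} {d.get('weight', 1.0)}\n")


# ----------------------------------------------------------------- routing

def _cancel_pass(gates: list[Gate]) -> list[Gate]:
    """Cancel adjacent inverse pairs (CNOT/CNOT, H/H) and merge Rz chains
    on the same qubit when nothing intervenes on that qubit."""
    out: list[Gate] = []
    for g in gates:
        if out:
            last = out[-1]
            if (g.name == last.name and g.qubits == last.qubits
                    and g.name in ("CNOT", "H", "X")):
                out.pop()
                continue
            if (g.name == "Rz" and last.name == "Rz"
                    and g.qubits == last.qubits
                    and not isinstance(g.param, (str, tuple))
                    and not isinstance(last.param, (str, tuple))):
                merged = float(last.param) + float(g.param)
                out.pop()
                if abs(merged) > 1e-12:
                    out.append(Gate("Rz", g.qubits, merged))
                continue
        out.append(g)
    return out


def route_and_count(c: CircuitIR, device: nx.Graph,
                    initial_layout: dict[int, int] | None = None):
    """Map the circuit onto the device by greedy SWAP insertion.

    Logical qubit i starts on device node ``initial_layout[i]`` (default:
    the i-th sorted device node).  Non-adjacent two-qubit gates trigger
    SWAPs (3 CNOTs each) along a shortest path, moving the control toward
    the target; the layout is updated and not restored.  Returns
    (routed CircuitIR over device-node indices, final layout, cnot count).
    """
    nodes = sorted(device.nodes())
    if initial_layout is None:
        if c.n_qubits > len(nodes):
            raise ValueError("device too small for circuit")
        layout = {i: nodes[i] for i in range(c.n_qubits)}
    else:
        layout = dict(initial_layout)
    node_index = {v: k for k, v in enumerate(nodes)}
    sp = dict(nx.all_pairs_shortest_path(device))
    routed = CircuitIR(len(nodes))
    for g in c.gates:
        if g.name not in _TWO_QUBIT:
            routed.gates.append(Gate(g.name,
                                     (node_index[layout[g.qubits[0]]],),
                                     g.param))
            continue
        lu, lv = g.qubits
        path = sp[layout[lu]][layout[lv]]
        # move logical qubit lu along the path until adjacent to lv
        while len(path) > 2:
            a, b = path[0], path[1]
            ia, ib = node_index[a], node_index[b]
            # SWAP(a, b) as three CNOTs
            routed.gates.append(Gate("CNOT", (ia, ib)))
            routed.gates.append(Gate("CNOT", (ib, ia)))
            routed.gates.append(Gate("CNOT", (ia, ib)))
            on_a = [l for l, p in layout.items() if p == a]
            on_b = [l for l, p in layout.items() if p == b]
            for l in on_a:
                layout[l] = b
            for l in on_b:
                layout[l] = a
            path = sp[layout[lu]][layout[lv]]
        routed.gates.append(Gate(g.name, (node_index[layout[lu]],
                                          node_index[layout[lv]]), g.param))
    routed.gates = _cancel_pass(routed.gates)
    return routed, layout, routed.cnot_count()
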