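# csvqe

Contextual-subspace VQE for molecular dissociation curves, end to end on a
classical simulator. The package targets the hard regime for quantum
chemistry on small quantum registers: bond breaking, where static
correlation makes single-reference methods fail, and where hybrid
quantum/classical subspace methods can compete with multiconfigurational
treatments at a fraction of the qubit cost. The bundled study is the
dissociation curve of molecular nitrogen in the STO-3G basis.

Everything runs from geometry with no external engines: a minimal
electronic-structure layer (McMurchie–Davidson Gaussian integrals,
restricted Hartree–Fock, MP2/CCSD/CCSD(T), determinant FCI/CISD/CASCI), a
symplectic Pauli algebra with Jordan–Wigner mapping, exact and noisy
statevector/density-matrix simulation, and the full error-mitigation stack
(measurement-error mitigation, zero-noise extrapolation, circuit tiling).

## The method

For a qubit Hamiltonian H = Σᵢ hᵢ Pᵢ:

1. **ℤ₂ tapering.** Independent Pauli symmetries (the GF(2) kernel of the
   symplectic matrix) are rotated onto single-qubit Z's and fixed to the
   Hartree–Fock sector. For N₂ there are five — spin-up/down parity plus
   three point-group generators — taking 20 qubits to 15 exactly.
2. **Noncontextual split.** A subset S of terms with transitive
   commutation among its non-symmetry elements is noncontextual: its
   spectrum is described by a classical objective over symmetry
   assignments q ∈ {±1}^|G| and a unit vector r of anticommuting-clique
   expectations,
   E(q, r) = Σ_B h_B ⟨B⟩_q + Σᵢ rᵢ Σ_{C∈Cᵢ} h_C ⟨C·Aᵢ⟩_q,
   minimised in closed form over r and by a Walsh–Hadamard transform over
   q (restricted to the Hartree–Fock reference sector by default).
3. **Contextual subspace.** Enforcing a subset of the noncontextual
   state's stabilizers over the full H — chosen greedily to maximise the
   ℓ₁-norm of the MP2 (or CCSD) excitation generator retained — projects
   H to n_q qubits. n_q = 0 recovers the noncontextual energy, the full
   register recovers FCI; in between, term count and ℓ₁-norm Λ = Σᵢ|hᵢ|
   shrink with the register.
4. **CS-DD / CS-VQE.** The reduced Hamiltonian is either diagonalized
   exactly (CS-DD) or optimised with a hardware-aware adaptive ansatz
   (qubit-ADAPT with a subgraph-isomorphism bias (1 − s(n)/W)^b toward a
   target device topology) on an exact or noisy sampled backend with
   MEM + ZNE.

A companion diagnostic s_δ(μ) averages an erf-regularised reciprocal
kernel over MO-energy combinations; its peaks along the scan flag orbital
crossings where the noncontextual branch switches.

## Worked example

```bash
python examples/02_contextual_subspace.py
```

prints, for N₂ at 1.4667 Å:

```
N2 at r = 1.4667 A
  HF energy            : -107.301390 Ha
  noncontextual energy : -107.394673 Ha (below HF: static correlation captured classically)
  CS-DD n_q= 0: -107.394673 Ha  (error vs FCI  5.4656 eV, 1 terms)
  CS-DD n_q= 5: -107.555562 Ha  (error vs FCI  1.0875 eV, 58 terms)
  CS-DD n_q=11: -107.595367 Ha  (error vs FCI  0.0044 eV, 1027 terms)
  CS-DD n_q=15: -107.595529 Ha  (error vs FCI  0.0000 eV, 2651 terms)
```

At this stretched geometry restricted HF is 8 eV above FCI; the classical
noncontextual solution already recovers a third of the missing
correlation, a 5-qubit subspace is within ~1 eV, 11 qubits reach
algorithmic accuracy (43 meV), and the full 15-qubit register is exact.
The other scripts in `examples/` walk through Hamiltonian construction
and tapering, the degeneracy diagnostic, adaptive-ansatz VQE, noisy
estimation with MEM + ZNE, and a mini benchmark scan.

A thin command-line front end mirrors the library for shell use, e.g.
`csvqe pec --grid 0.8 1.2 1.6 2.0 -n 5 -g MP2`.

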