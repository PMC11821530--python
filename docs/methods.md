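# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the tests do and do not establish.

## Electronic structure layer

Integrals are McMurchie–Davidson over contracted Cartesian Gaussians with
the standard published STO-3G parameters (H, He, Li, C, N, O bundled);
only s/p shells are exercised. The restricted Hartree–Fock driver uses a
damped-Roothaan start followed by DIIS; convergence targets are 1e-11 Ha
on the energy and 1e-7 on the orbital-gradient norm. Two reliability
measures matter for dissociation scans:

- **Scan continuation.** Cold starts from the core-Hamiltonian guess are
  reliable near equilibrium but can land on high-lying restricted
  stationary points beyond ~1.3 Å, where several closed-shell
  configurations compete. Stretched diatomics are therefore converged by
  warm-starting along a short bond-length ladder from an anchor at
  1.15 Å (step 0.1 Å), which keeps the whole curve on the single smooth
  aufbau branch that standard restricted references trace. The study
  object additionally warm-starts each new scan point from its nearest
  cached neighbour (within 0.12 Å).
- **Orbital purification.** Degenerate canonical orbitals (the π pairs,
  and transiently the core σ pair) come out of the eigensolver in an
  arbitrary mixture, which hides the exact binary point-group structure
  of the Jordan–Wigner coefficients (only 4 instead of 5 ℤ₂ symmetries
  are then detected). Degenerate blocks are resolved by diagonalising the
  projector onto one molecule-frame transverse p direction — a
  rotation-covariant choice — and orbital signs are fixed by making each
  orbital's largest coefficient positive.

Correlation methods are spin-orbital: MP2, CCSD (Stanton–Gauss–Watts–
Bartlett residuals with DIIS), perturbative triples, and determinant CI
(FCI/CISD/CASCI) assembled from per-spin single-excitation operators.
CCSD equals FCI for two-electron systems to 1e-9 Ha, and the determinant
FCI agrees with exact diagonalization of the Jordan–Wigner Hamiltonian —
two routes that share only the integrals — which is the package's primary
correctness anchor. CASCI active spaces are selected from MP2
natural-orbital occupations: orbitals are ranked by occupation, the most
occupied become the closed core (which fixes the electron count) and the
next M_act form the active window. An orbital-optimised CASSCF is not
provided; CASCI in the natural-orbital basis is the multiconfigurational
benchmark.

Conventions, stated once: spin orbitals interleave as s = 2p + σ
(σ = 0 for α), |1⟩ means occupied, qubit 0 is the leftmost character of a
Pauli string and the most significant bit of a basis index. The
Hartree–Fock determinant is therefore the bit-string 1…10…0.

## Noncontextual model and its solver

A term set is noncontextual when commutation restricted to its
non-symmetry elements is transitive (universally-commuting part Z′ plus
cliques with inter-clique anticommutation). The classical objective over
(q, r) is minimised with r in closed form and q by an exhaustive
Walsh–Hadamard transform (annealing fallback above 20 free generators,
never triggered at this scale). Unit tests verify on random instances
that the objective minimum equals the exact ground energy of the
noncontextual part.

Two deliberate design choices shape the default pipeline; both arose from
studying the physics of the tapered register:

- **Reference-sector solve.** The tapered register fixes only symmetry
  *parities*, so it contains states of the wrong particle number and spin
  projection, and the *unconstrained* objective minimum generally lands
  in such an unphysical sector (an artefact state well below any physical
  determinant). By default the symmetry-generator assignments that the
  Hartree–Fock reference determines (via back-mapping through the
  tapering Cliffords) are clamped to it, and only the remaining
  directions are searched. The stabilizer eigenvalues used for the
  subspace projection inherit this sector, which is what makes the
  reduced Hamiltonians describe the molecule rather than an ion. The
  free solver remains available (`solve_noncontextual(..., reference=None)`).
- **Excitation-multiplet clique selection.** The default term-selection
  strategy admits all diagonal terms first; off-diagonal terms are then
  grouped by the determinant D their back-mapped image excites the
  reference to, each group is scored by the estimated two-level lowering
  √(ΔE²/4 + K²) − |ΔE|/2 with the *physical* coupling K = |⟨D|H|HF⟩|
  (the signed sum over the whole Jordan–Wigner multiplet) and the
  diagonal gap ΔE, and groups are offered to the greedy in that order.
  Scoring whole multiplets by their matrix element is essential on two
  counts. A plain per-term magnitude ordering locks onto a large but
  energetically inert core-pair exchange clique (whose multiplet
  coupling cancels) and never captures the valence pair excitation that
  stabilises the stretched molecule. And per-term weights are unstable
  under the arbitrary degenerate-orbital frame: tiny SCF differences
  reorder near-tied terms and produced isolated branch hops along fine
  scans, whereas the multiplet coupling is frame-robust (fine scans
  agree across different warm-start histories to 1e-11 Ha). With this
  strategy the noncontextual energy tracks the CASCI(4o,2e) curve to a
  few tenths of a mHa over the entire scan — the noncontextual ground
  state is exactly the two-configuration mixture a minimal CAS captures
  — and the curve is smooth: the sharp branch switches that a
  magnitude-greedy selection produces at orbital crossings do not occur
  here, so the discontinuity detector reports no events for the bundled
  study (it is exercised on synthetic curves in the tests).

## Stabilizer selection and projection

Stabilizers are drawn from the span of the noncontextual model's
symmetry generators together with the clique operator Σᵢ rᵢ Aᵢ, which a
Givens-rotation sequence first maps onto a single Pauli. The nested
greedy picks one stabilizer at a time maximising the ℓ₁-norm of guide
terms (MP2 or CCSD excitation generator, tapered and clique-rotated)
commuting with every choice; prefixes of one ordering serve every
subspace size, making the retained score monotone. Near-ties — candidates
within 1% of the best retained guide ℓ₁ — are re-ranked by the
Hamiltonian ℓ₁-norm they retain, with exact ties broken lexicographically.
The secondary criterion exists because a doubles-only guide is blind to
the singles sector: without it, an apparently free stabilizer choice
silently destroys ~70 meV of singles correlation at every subspace size
above 10 qubits. A beam-search refinement over stabilizer subgroups was
evaluated; it improves the retained ℓ₁ slightly but never changed a
subspace energy, so the nested greedy is the default.

Projection rotates each chosen stabilizer to a single-qubit Z, substitutes
its eigenvalue, drops terms that fail to commute (this is the contextual
approximation; in tapering, where no term fails, the projection is exact)
and removes the fixed qubits. Endpoints are exact by construction:
zero remaining qubits reproduce the noncontextual energy and the full
register reproduces FCI (both asserted at 1e-7 Ha).

## Adaptive ansatz and simulated hardware

The pool is the set of individual Pauli strings of the projected UCCSD
excitation generator. Scoring uses |i⟨[H, P]⟩| (equal to the
parameter-shift derivative at zero; both evaluated in tests), times the
hardware bias (1 − s(n)/W)^b when a target topology is given, with
defaults D = 2 deleted nodes and b = 1. Ties break by smaller compiled
two-qubit count, then lexicographically. Re-optimisation is BFGS with
parameter-shift gradients (tolerance 1e-6, 200 iterations); the run stops
when the pool-gradient ℓ₁ falls below 1e-3 Ha (after one seeded 1e-3
parameter perturbation to escape symmetric plateaus) or at a cycle cap.
Initial states are the projection of the Hartree–Fock determinant into
the reduced register, whose energy equals E_HF there exactly.

Routing onto a device graph is greedy nearest-neighbour SWAP insertion
along shortest paths (3 CNOTs per SWAP) with an inverse-cancellation
pass; it is deterministic and adequate for relative depth comparisons,
not an optimal transpiler.

The noisy backend is a density-matrix simulator with gate-located
depolarizing channels (defaults p₁ = 1e-4, p₂ = 5e-3, roughly
contemporary superconducting-device error rates) and a terminal
per-qubit readout-confusion matrix (default flip probabilities 2%/4%).
There is no idle-decoherence channel, so pulse-level dynamical-decoupling
techniques have no effect here and are not modelled. Measurement-error
mitigation inverts the tensor-product confusion matrix, clipping negative
quasi-probabilities to zero and renormalising (a least-squares projection
would be the alternative). ZNE replaces each CNOT by
Had·[CPhase(π/λ)]^λ·Had re-expressed natively (2λ CNOT and 3λ+2
single-qubit gates per original CNOT, exactly unitary-preserving), with
gain factors G(λ) computed as the ratio of expected error-event counts
(p₁·#1q + p₂·#2q) to the λ = 1 circuit — a documented stand-in for
device-calibrated gains — and inverse-variance-weighted polynomial
extrapolation to G = 0 (λ grid {1, 2, 3}, linear by default, quadratic
with four or more points). Tiling packs disjoint clusters embedding the
ansatz coupling graph (a specialised low-degree-first path packer reaches
5 tiles on the bundled 27-qubit heavy-hex layout and 3 on the 16-qubit
one; the 125-qubit heavy-hex patch generated for Eagle-scale experiments
is a synthetic lattice, where the packer reaches 24 tiles); per-tile
noise parameters are drawn from ±50% ranges around the defaults to
emulate spatial inhomogeneity, and the reported energy is the tile mean
with its standard error.

## Degeneracy diagnostic

s_δ(μ) is evaluated exactly as defined over all index tuples up to
D_max (default: full depth for M ≤ 10), with the removable x → 0
singularity of the kernel set to its limit 1 and δ = 0 reducing to exact
degeneracy detection. μ is used in the ascending order the SCF returns;
the tuple structure makes depths ≥ 3 order-dependent, which is why the
convention is fixed and only the pairwise layer is asserted
permutation-invariant. The default filter δ = 0.05 Ha resolves the
valence crossings of the bundled study without washing them out. The
metric is reproduced as defined, not calibrated; the test is the
qualitative coincidence of its peaks with noncontextual branch switches.

## Derived scan quantities and problem sizes

Fine-structure quantities use an adaptive pattern chosen to keep the full
study on one CPU in minutes: non-variationality onsets scan a 20 mÅ grid
and bisect the first sign change to 1 mÅ; the equilibrium length refines
a 20 mÅ bracket by interval shrinking plus a final parabolic fit;
noncontextual discontinuities scan an 8 mÅ grid, flag steps exceeding ten
times the locally-windowed median neighbour gap (the local window keeps
the steep-but-smooth repulsive wall from triggering), and re-scan flagged
windows at 2 mÅ. eV↔Hartree uses 27.211386245988; "algorithmic accuracy"
means 43 meV against FCI in the same basis. Simulated-hardware runs use
5000 shots per QWC clique and 5 tiles, mirroring a 27-qubit-device
configuration.

## Known limitations

- Open-shell references are not implemented; the restricted driver
  serves all closed-shell singlets studied (where ROHF = RHF).
- The noncontextual branch structure depends on the selection heuristic.
  Our default produces one discontinuity (at the 0.94 Å crossing) and
  the CASCI-coincident branch beyond it; other heuristics produce other
  branch patterns, and the package makes no claim that its branch
  positions are canonical.
- The MP2-guided subspaces are systematically weaker than CCSD-guided
  ones at stretched geometries (both reach algorithmic accuracy at 11
  qubits under the default tie-breaking).
- Gain factors, the routing pass and the tiler are deterministic
  simplifications of device-calibrated procedures; only relative
  comparisons should be read from them.
- The noisy simulator is limited to small registers (density matrices)
  and carries no idle decoherence or correlated readout.
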