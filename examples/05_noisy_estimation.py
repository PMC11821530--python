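"""Shot-based estimation with readout mitigation and zero-noise
extrapolation on a small fixture.

A two-qubit circuit is measured in qubit-wise-commuting groups on a
simulated backend with depolarizing gate noise and biased readout.  MEM
inverts the readout-confusion channel; ZNE amplifies the CNOT noise via
the CPhase root decomposition and extrapolates the energy to zero gain.
"""

import numpy as np

from csvqe.circuits import CircuitIR
from csvqe.measurement import (NoiseModel, ZNEConfig, estimate_energy,
                               qwc_partition, zne_energy)
from csvqe.paulis import PauliSum

H = PauliSum.from_strings({"ZI": 0.6, "IZ": 0.3, "XX": 0.5, "YY": -0.2})
circ = CircuitIR(2)
circ.add("Ry", 0, 0.9).add("CNOT", (0, 1)).add("Ry", 1, -0.4)

exact = H.expectation(circ.statevector())
grouping = qwc_partition(H)
print(f"{len(grouping.groups)} QWC measurement groups:",
      [g[0] for g in grouping.groups])

noise = NoiseModel.uniform(2, p1=1e-4, p2=5e-3, p01=0.03, p10=0.05)
raw, raw_err = estimate_energy(H, circ, noise=noise, shots=5000, seed=3)
res = zne_energy(H, circ, None, noise, ZNEConfig((1, 2, 3), 1, 5000),
                 seed=3)
print(f"exact energy       : {exact:+.5f}")
print(f"raw noisy estimate : {raw:+.5f}  (error {abs(raw - exact):.5f})")
print(f"gains G(lambda)    : {np.round(res.gains, 3)}")
print(f"MEM+ZNE estimate   : {res.extrapolated:+.5f}  "
      f"(error {abs(res.extrapolated - exact):.5f})")
print("Mitigation trades bias for variance: the extrapolated value sits "
      "closer to the exact energy.")
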