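"""Molecular-orbital degeneracy diagnostic along the dissociation scan.

The detection function averages an erf-regularised reciprocal kernel over
orbital-energy combinations: values near 1 signal (near-)degenerate MO
levels.  Peaks along the bond-length scan mark orbital crossings, where
static correlation builds up and the noncontextual energy switches
branch.
"""

import numpy as np

from csvqe.pipeline import DiatomicStudy
from csvqe.degeneracy import local_maxima

study = DiatomicStudy()
rs = np.round(np.arange(0.85, 1.60001, 0.05), 3)
vals = study.degeneracy_curve(rs, delta=0.05)
print(" r [A]   s_delta")
for r, v in zip(rs, vals):
    bar = "#" * int(40 * v)
    print(f" {r:.2f}   {v:.4f}  {bar}")
peaks = local_maxima(rs, vals)
print("local maxima near:", peaks, "(orbital crossings)")
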