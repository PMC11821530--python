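"""Molecular-orbital degeneracy detection.

Given the vector mu of M canonical MO energies, the detection function
averages an erf-regularised reciprocal kernel over all ordered index
tuples j_1 < ... < j_i up to depth D_max,

    s_delta(mu) = (delta sqrt(pi) / 2) / (D_max - 1)
                  * sum_{i=2}^{D_max} C(M, i)^{-1}
                    sum_{j_1<...<j_i} erf(x / delta) / x,
    x = mu_{j_i} - sum_{k<i} mu_{j_k},

where delta >= 0 filters near-degeneracy: each tuple's kernel lies in
[0, 1], approaching 1 as x -> 0, and as delta -> 0 the kernel becomes the
Kronecker delta on exact degeneracy x = 0.  The value is bounded in
[0, 1] and is non-decreasing in delta.  Peaks along a bond-length scan
flag orbital (near-)crossings, which is where static correlation builds
up and single-reference perturbation theory degrades.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.special import erf

__all__ = ["DegeneracyQuery", "s_delta", "degeneracy_scan", "local_maxima"]


@dataclass
class DegeneracyQuery:
    mu: np.ndarray        # canonical MO energies (Hartree), engine order
    delta: float          # filtering parameter (Hartree), >= 0
    d_max: int | None = None   # truncation depth, 2 <= d_max <= M

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        M = len(self.mu)
        if self.d_max is None:
            self.d_max = M
        if not 2 <= self.d_max <= M:
            raise ValueError(f"d_max must lie in [2, {M}]")


def _kernel(x: np.ndarray, delta: float) -> np.ndarray:
    """delta*sqrt(pi)*erf(x/delta)/(2x) with its removable limits."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    small = np.abs(x) < 1e-12
    if delta == 0.0:
        out[small] = 1.0
        return out
    out[small] = 1.0
    xs = x[~small]
    with np.errstate(over="ignore"):
        out[~small] = delta * np.sqrt(np.pi) * erf(xs / delta) / (2.0 * xs)
    return out


def s_delta(q: DegeneracyQuery) -> float:
    """Evaluate the degeneracy-detection function; result lies in [0, 1]."""
    mu = q.mu
    M = len(mu)
    total = 0.0
    for depth in range(2, q.d_max + 1):
        xs = []
        for tup in combinations(range(M), depth):
            xs.append(mu[tup[-1]] - mu[list(tup[:-1])].sum())
        total += _kernel(np.array(xs), q.delta).sum() / comb(M, depth)
    return float(total / (q.d_max - 1))


def degeneracy_scan(mu_per_r: dict[float, np.ndarray], delta: float,
                    d_max: int | None = None):
    """Evaluate s_delta along a bond-length scan.

    Returns (r values ascending, s values) as arrays.
    """
    rs = np.array(sorted(mu_per_r))
    vals = np.array([s_delta(DegeneracyQuery(mu_per_r[r], delta, d_max))
                     for r in rs])
    return rs, vals


def local_maxima(rs: np.ndarray, vals: np.ndarray) -> list[float]:
    """Interior local maxima of a sampled curve (strict on one side)."""
    peaks = []
    for i in range(1, len(vals) - 1):
        if vals[i] >= vals[i - 1] and vals[i] > vals[i + 1]:
            peaks.append(float(rs[i]))
        elif vals[i] > vals[i - 1] and vals[i] >= vals[i + 1]:
            peaks.append(float(rs[i]))
    return sorted(set(peaks))
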