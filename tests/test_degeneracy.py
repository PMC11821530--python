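"""MO degeneracy detection function: limits, bounds, monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from csvqe.degeneracy import (DegeneracyQuery, degeneracy_scan, local_maxima,
                              s_delta)


def test_exact_degeneracy_limit():
    # delta = 0 detects exact degeneracy via the Kronecker limit
    assert s_delta(DegeneracyQuery(np.array([1.0, 1.0]), 0.0, 2)) == 1.0
    assert s_delta(DegeneracyQuery(np.array([0.0, 1.0]), 0.0, 2)) == 0.0


def test_parameter_validation():
    with pytest.raises(ValueError):
        DegeneracyQuery(np.arange(4.0), -0.1)
    with pytest.raises(ValueError):
        DegeneracyQuery(np.arange(4.0), 0.1, d_max=1)
    with pytest.raises(ValueError):
        DegeneracyQuery(np.arange(4.0), 0.1, d_max=5)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10 ** 6), delta=hst.floats(0.0, 2.0))
def test_bounded_between_zero_and_one(seed, delta):
    mu = np.random.default_rng(seed).standard_normal(6)
    v = s_delta(DegeneracyQuery(mu, delta))
    assert 0.0 <= v <= 1.0 + 1e-12


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=hst.integers(0, 10 ** 6),
       d1=hst.floats(0.01, 1.0), d2=hst.floats(0.01, 1.0))
def test_monotone_in_delta(seed, d1, d2):
    mu = np.random.default_rng(seed).standard_normal(5)
    lo, hi = sorted((d1, d2))
    assert s_delta(DegeneracyQuery(mu, lo)) <= \
        s_delta(DegeneracyQuery(mu, hi)) + 1e-12


def test_truncation_depth_consistency():
    # deeper truncation never loses exact-degeneracy contributions
    mu = np.array([0.3, 0.3, 0.9, 1.2, 1.2])
    vals = [s_delta(DegeneracyQuery(mu, 0.0, d)) for d in range(2, 6)]
    assert all(v >= 0 for v in vals)
    # the pairwise layer alone already sees both degenerate pairs
    assert vals[0] > 0


def test_pairwise_layer_permutation_invariant():
    rng = np.random.default_rng(8)
    mu = rng.standard_normal(6)
    v1 = s_delta(DegeneracyQuery(mu, 0.2, 2))
    v2 = s_delta(DegeneracyQuery(mu[::-1].copy(), 0.2, 2))
    assert abs(v1 - v2) < 1e-12


def test_synthetic_level_crossing_produces_single_peak():
    # two levels crossing at r = 1.5 on an otherwise spread spectrum
    rs = np.round(np.arange(1.0, 2.01, 0.05), 3)
    curves = {}
    for r in rs:
        mu = np.array([-10.0, -5.0, -1.0 + (r - 1.5), -1.0 - (r - 1.5), 4.0])
        curves[float(r)] = mu
    grid, vals = degeneracy_scan(curves, delta=0.05, d_max=2)
    peaks = local_maxima(grid, vals)
    assert peaks == [1.5]


def test_constant_spectrum_gives_flat_curve():
    mu = np.array([0.0, 1.0, 2.0])
    curves = {r: mu for r in (1.0, 1.1, 1.2, 1.3)}
    grid, vals = degeneracy_scan(curves, delta=0.1)
    assert np.allclose(vals, vals[0])
    assert local_maxima(grid, vals) == []
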