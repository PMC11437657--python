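"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own gradient and
propagation code paths: finite differences of the scalar energy, explicit
double-loop linear algebra, and dense grid search.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

from confpc import energy, init_params, make_state

logging.getLogger("confpc").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240913)


def fd_energy_grad_u(params, state, level, h=1e-5):
    """Central finite differences of the energy w.r.t. one level's potentials."""
    g = np.zeros_like(state.u[level])
    for i in range(g.size):
        up = [x.copy() for x in state.u]
        dn = [x.copy() for x in state.u]
        up[level][i] += h
        dn[level][i] -= h
        e_up = energy(params, make_state(params, up, state.clamped))
        e_dn = energy(params, make_state(params, dn, state.clamped))
        g[i] = (e_up - e_dn) / (2 * h)
    return g


def fd_energy_grad_matrix(params, state, which, level, h=1e-6):
    """Finite differences of the energy w.r.t. entries of W[level] or A[level]."""
    mat = getattr(params, which)[level]
    g = np.zeros_like(mat)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            for sgn, store in ((+1, "up"), (-1, "dn")):
                p2 = params.copy()
                getattr(p2, which)[level][i, j] += sgn * h
                st2 = make_state(p2, [x.copy() for x in state.u], state.clamped)
                if sgn > 0:
                    e_up = energy(p2, st2)
                else:
                    e_dn = energy(p2, st2)
            g[i, j] = (e_up - e_dn) / (2 * h)
    return g


def random_offfloor_network(rng, activation=None, max_levels=4, max_size=5, w_scale=0.3):
    """Random small network and a consistent state kept off the confidence
    floor and away from the rectifier kink (positive potentials above the
    observation level)."""
    n_levels = int(rng.integers(2, max_levels + 1))
    sizes = [int(s) for s in rng.integers(1, max_size + 1, size=n_levels)]
    if activation is None:
        activation = ["rectifier", "softplus", "identity"][int(rng.integers(3))]
    params = init_params(
        sizes, activation=activation, seed=int(rng.integers(2**31)), w_scale=w_scale
    )
    u = [rng.normal(size=sizes[0])] + [
        rng.uniform(0.1, 1.5, size=d) for d in sizes[1:]
    ]
    state = make_state(params, u, [False] * n_levels)
    return params, state


def rel_err(a, b):
    scale = max(float(np.max(np.abs(a))), float(np.max(np.abs(b))), 1e-8)
    return float(np.max(np.abs(np.asarray(a) - np.asarray(b)))) / scale
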