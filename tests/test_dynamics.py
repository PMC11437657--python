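"""Tests for the Euler inference dynamics: error propagation, fixed points,
descent, Bayesian equilibria, and the classical baseline."""

import io

import numpy as np
import pytest

from confpc import (
    NetworkParams,
    NumericalError,
    SimulationConfig,
    classical_pc_inference,
    energy,
    energy_gradient,
    export_trajectory,
    inference_step,
    init_params,
    make_state,
    run_inference,
    total_propagated_error,
)

from conftest import random_offfloor_network, rel_err


# ---------------------------------------------------------------------------
# total propagated error
# ---------------------------------------------------------------------------

def test_total_propagated_error_zero_without_errors():
    p = init_params([2, 2], seed=1)
    st = make_state(p, [np.zeros(2), np.ones(2)], [True, False])
    st.e[0] = np.zeros(2)
    st.delta[0] = np.zeros(2)
    np.testing.assert_allclose(total_propagated_error(p, st, 1), 0.0, atol=1e-15)


def test_total_propagated_error_scalar_chain_value():
    """W=A=1, pi=2, e=0.5 => delta=0.125 and a = 2*0.5 + 0.125 = 1.125."""
    p = NetworkParams(
        [1, 1], W=[np.array([[1.0]])], A=[np.array([[1.0]])], activation="identity"
    )
    st = make_state(p, [np.array([2.5]), np.array([2.0])], [True, False])
    np.testing.assert_allclose(st.pi[0], [2.0])
    np.testing.assert_allclose(st.e[0], [0.5])
    np.testing.assert_allclose(st.delta[0], [0.125])
    np.testing.assert_allclose(total_propagated_error(p, st, 1), [1.125])


def test_total_propagated_error_level_zero_raises():
    p = init_params([2, 2], seed=1)
    st = make_state(p, [np.zeros(2), np.ones(2)], [False, False])
    with pytest.raises(IndexError):
        total_propagated_error(p, st, 0)


def test_total_propagated_error_matches_finite_difference_of_lower_term(rng):
    """a_l equals minus the finite-difference derivative, w.r.t. u_l, of the
    level-(l-1) energy term computed by an independent double loop."""

    def lower_term(params, u, level):
        # explicit sums, no library linear algebra
        r_above = [max(x, 0.0) for x in u[level]]
        total = 0.0
        for i in range(params.layer_sizes[level - 1]):
            mu_i = sum(params.W[level - 1][i, j] * r_above[j] for j in range(len(r_above)))
            pi_i = max(
                sum(params.A[level - 1][i, j] * r_above[j] for j in range(len(r_above))),
                1e-6,
            )
            e_i = u[level - 1][i] - mu_i
            total += 0.5 * pi_i * e_i**2 - 0.5 * np.log(pi_i)
        return total

    for _ in range(10):
        params, state = random_offfloor_network(rng, activation="rectifier")
        for level in range(1, params.n + 1):
            a = total_propagated_error(params, state, level)
            h = 1e-6
            a_fd = np.zeros_like(a)
            for i in range(a.size):
                up = [x.copy() for x in state.u]
                dn = [x.copy() for x in state.u]
                up[level][i] += h
                dn[level][i] -= h
                a_fd[i] = -(
                    lower_term(params, up, level) - lower_term(params, dn, level)
                ) / (2 * h)
            assert rel_err(a, a_fd) < 1e-4


# ---------------------------------------------------------------------------
# single steps
# ---------------------------------------------------------------------------

def test_inference_step_fixed_point_in_fixed_confidence_mode():
    """u = mu everywhere with constant confidences: nothing moves."""
    p = init_params([2, 3, 2], activation="identity", seed=3)
    u2 = np.array([0.7, 1.1])
    u1 = u2 @ p.W[1].T
    u0 = u1 @ p.W[0].T
    cfg = SimulationConfig(fixed_pi=[np.ones(2), np.ones(3)])
    st = make_state(p, [u0, u1, u2], [True, False, False], cfg)
    new = inference_step(p, st, cfg)
    for a, b in zip(st.u, new.u):
        np.testing.assert_allclose(a, b, atol=1e-14)


def test_inference_step_all_clamped_is_identity(rng):
    params, state = random_offfloor_network(rng)
    state.clamped = [True] * (params.n + 1)
    new = inference_step(params, state, SimulationConfig())
    for a, b in zip(state.u, new.u):
        np.testing.assert_allclose(a, b, rtol=0, atol=0)
    res = run_inference(params, state, SimulationConfig())
    assert res.converged and res.steps_taken == 0


def test_inference_step_scalar_chain_hand_computed():
    """One Euler step on a [1,1,1] identity chain against hand arithmetic."""
    w0, w1, a0, a1 = 1.5, 0.5, 0.8, 1.2
    p = NetworkParams(
        [1, 1, 1],
        W=[np.array([[w0]]), np.array([[w1]])],
        A=[np.array([[a0]]), np.array([[a1]])],
        activation="identity",
        tau=1.0,
    )
    u0, u1, u2 = 2.0, 1.0, 0.5
    dt = 0.1
    cfg = SimulationConfig(dt=dt)
    st = make_state(p, [np.array([u0]), np.array([u1]), np.array([u2])], [True, False, False])
    new = inference_step(p, st, cfg)

    pi0, mu0 = a0 * u1, w0 * u1
    pi1, mu1 = a1 * u2, w1 * u2
    e0, e1 = u0 - mu0, u1 - mu1
    d0 = (1 / pi0 - e0**2) / 2
    d1 = (1 / pi1 - e1**2) / 2
    a_1 = w0 * pi0 * e0 + a0 * d0
    a_2 = w1 * pi1 * e1 + a1 * d1
    u1_next = u1 + dt * (-u1 + mu1 + a_1 / pi1)
    u2_next = u2 + dt * a_2
    assert new.u[1][0] == pytest.approx(u1_next, rel=1e-12)
    assert new.u[2][0] == pytest.approx(u2_next, rel=1e-12)
    assert new.u[0][0] == u0  # clamped


def test_step_equals_metric_scaled_energy_gradient(rng):
    """One Euler step must equal explicit Euler on -pi^{-1} o dE/du (interior
    and observation) and on -dE/du at the uniform-prior top, to 1e-10."""
    for _ in range(10):
        params, state = random_offfloor_network(rng)
        cfg = SimulationConfig(dt=0.05)
        new = inference_step(params, state, cfg)
        scale = cfg.dt / params.tau
        n = params.n
        for level in range(n + 1):
            g = energy_gradient(params, state, level)
            if level == n:
                expected = state.u[level] - scale * g
            else:
                expected = state.u[level] - scale * g / state.pi[level]
            assert float(np.max(np.abs(new.u[level] - expected))) < 1e-10


# ---------------------------------------------------------------------------
# full relaxations
# ---------------------------------------------------------------------------

def test_energy_descends_along_dynamics(rng):
    """With positive rates (softplus) and the default step size, the energy
    is non-increasing along the relaxation (tolerance 1e-9 per step)."""
    for _ in range(5):
        params, state = random_offfloor_network(rng, activation="softplus")
        state.clamped = [True] + [False] * params.n
        cfg = SimulationConfig(max_steps=300, record_trajectory=True)
        res = run_inference(params, state, cfg)
        diffs = np.diff(res.energy_trace)
        assert np.all(diffs <= 1e-9)


def test_fixed_confidence_equilibrium_is_precision_weighted_mean():
    """Scalar chain, constant confidences: the latent settles at
    (pi_0 u_0 + pi_1 mu_1) / (pi_0 + pi_1)."""
    u0, mu1 = 2.0, -1.0
    for pi0, pi1 in [(0.5, 2.0), (3.0, 1.0), (1.0, 1.0)]:
        p = NetworkParams(
            [1, 1, 1],
            W=[np.array([[1.0]]), np.array([[mu1]])],
            A=[np.ones((1, 1)), np.ones((1, 1))],
            activation="identity",
        )
        cfg = SimulationConfig(fixed_pi=[np.array([pi0]), np.array([pi1])], tol=1e-10)
        st = make_state(
            p, [np.array([u0]), np.array([0.0]), np.array([1.0])], [True, False, True], cfg
        )
        res = run_inference(p, st, cfg)
        expected = (pi0 * u0 + pi1 * mu1) / (pi0 + pi1)
        assert res.converged
        assert res.final_state.u[1][0] == pytest.approx(expected, abs=1e-6)


def test_gain_modulation_by_data_and_prior_confidence():
    """The equilibrium weight on the data is increasing in the data
    confidence pi_0 (multiplicative) and decreasing in the prior confidence
    pi_1 (divisive)."""
    u0, mu1 = 1.0, 0.0

    def eq_weight(pi0, pi1):
        p = NetworkParams(
            [1, 1, 1],
            W=[np.array([[1.0]]), np.array([[mu1]])],
            A=[np.ones((1, 1)), np.ones((1, 1))],
            activation="identity",
        )
        cfg = SimulationConfig(fixed_pi=[np.array([pi0]), np.array([pi1])], tol=1e-10)
        st = make_state(
            p, [np.array([u0]), np.array([0.5]), np.array([1.0])], [True, False, True], cfg
        )
        res = run_inference(p, st, cfg)
        return res.final_state.u[1][0] / u0  # mu1 = 0 so u_eq/u0 is the data weight

    grid = [0.25, 0.5, 1.0, 2.0, 4.0]
    for pi1 in grid:
        weights = [eq_weight(pi0, pi1) for pi0 in grid]
        assert np.all(np.diff(weights) > 0)
    for pi0 in grid:
        weights = [eq_weight(pi0, pi1) for pi1 in grid]
        assert np.all(np.diff(weights) < 0)


def test_equilibrium_energy_matches_grid_search(rng):
    """Full model, one free scalar latent at the top: the relaxed energy
    matches a dense 1-D grid search over the latent."""
    for _ in range(6):
        d0 = int(rng.integers(2, 5))
        params = init_params(
            [d0, 1], activation="softplus", seed=int(rng.integers(2**31)), w_scale=0.3
        )
        x = rng.normal(size=d0)
        cfg = SimulationConfig(max_steps=10_000, tol=1e-9)
        st = make_state(params, [x, np.array([0.5])], [True, False], cfg)
        res = run_inference(params, st, cfg)
        e_dyn = energy(params, res.final_state)

        grid = np.arange(-10.0, 10.0, 1e-4)[:, None]
        gstate = make_state(
            params, [np.broadcast_to(x, (grid.shape[0], d0)), grid], [True, True], cfg
        )
        e_grid = float(np.min(energy(params, gstate, aggregate=False)))
        assert abs(e_dyn - e_grid) < 1e-3


def test_classical_equals_full_dynamics_at_unit_fixed_confidence(rng):
    """The classical baseline must coincide with the confidence dynamics run
    at pi == 1 with the second-order pathway off."""
    params, state = random_offfloor_network(rng, activation="rectifier")
    state.clamped = [True] + [False] * params.n
    cfg_fixed = SimulationConfig(
        max_steps=50, fixed_pi=[np.ones(d) for d in params.layer_sizes[:-1]]
    )
    cfg_plain = SimulationConfig(max_steps=50)
    res_fixed = run_inference(
        params, make_state(params, state.copy_potentials(), state.clamped, cfg_fixed), cfg_fixed
    )
    res_classical = classical_pc_inference(
        params, make_state(params, state.copy_potentials(), state.clamped, cfg_plain), cfg_plain
    )
    for a, b in zip(res_fixed.final_state.u, res_classical.final_state.u):
        np.testing.assert_allclose(a, b, atol=1e-12)


def test_divergent_dynamics_raise_named_numerical_error():
    # linear fixed-confidence chain whose Euler map has spectral radius ~100
    p = NetworkParams(
        [1, 1, 1],
        W=[np.array([[10.0]]), np.array([[0.0]])],
        A=[np.ones((1, 1)), np.ones((1, 1))],
        activation="identity",
    )
    cfg = SimulationConfig(
        dt=1.0, max_steps=5000, fixed_pi=[np.array([1.0]), np.array([1.0])]
    )
    st = make_state(p, [np.array([1.0]), np.array([1.0]), np.array([0.0])], [True, False, True], cfg)
    with pytest.raises(NumericalError, match="step"):
        run_inference(p, st, cfg)


def test_trajectory_export_is_parseable(rng):
    params, state = random_offfloor_network(rng, activation="softplus")
    state.clamped = [True] + [False] * params.n
    cfg = SimulationConfig(max_steps=20, record_trajectory=True)
    res = run_inference(params, state, cfg)
    buf = io.StringIO()
    export_trajectory(res, buf)
    lines = [ln for ln in buf.getvalue().splitlines() if not ln.startswith("#")]
    header = lines[0].split("\t")
    assert header[:2] == ["step", "energy"]
    assert len(lines) - 1 == len(res.energy_trace)
    first = lines[1].split("\t")
    assert float(first[1]) == pytest.approx(res.energy_trace[0])
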