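"""Inference dynamics: leaky gradient descent on the energy.

Representations relax by explicit Euler integration of

    tau du_l/dt = -pi_l^{-1} o dE/du_l = -u_l + mu_l + pi_l^{-1} o a_l,

where the total propagated error ``a_l`` combines confidence-weighted
first-order errors and second-order errors rising from the level below.
The local confidence ``pi_l`` acts as a metric (an approximate second-order
preconditioner), so a neuron's integration of bottom-up errors is divisively
controlled by the confidence of the predictions it receives, while the
confidence of the predictions it sends multiplies the errors it propagates.

The top level has a uniform prior, hence no leak: it integrates the pure
bottom-up gradient ``tau du_n/dt = a_n``. The observation level, when
unclamped, relaxes toward its top-down mean.

A classical predictive-coding baseline (unit confidence, no second-order
pathway) and a fixed-confidence diagnostic mode (constant ``pi``, exposing
the closed-form precision-weighted equilibria) share the same integrator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, TextIO

import numpy as np

from .model import (
    NetworkParams,
    NetworkState,
    NumericalError,
    SimulationConfig,
    _bottom_up,
    energy,
    energy_gradient,
    refresh,
)

__all__ = [
    "InferenceResult",
    "total_propagated_error",
    "inference_step",
    "run_inference",
    "classical_pc_inference",
    "export_trajectory",
]


@dataclass
class InferenceResult:
    """Outcome of one relaxation run.

    ``level_trace`` holds, when trajectories are recorded, one row per
    recorded step with ``(max|e_l|, max|delta_l|)`` for each level.
    """

    final_state: NetworkState
    steps_taken: int
    converged: bool
    energy_trace: list[float]
    max_gradient_norm: float
    level_trace: list[list[tuple[float, float]]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.level_trace is None:
            self.level_trace = []


def total_propagated_error(
    params: NetworkParams,
    state: NetworkState,
    level: int,
    mode: str = "confidence",
    _sign: float = 1.0,
) -> np.ndarray:
    """Total error ``a_l`` rising into ``level`` from the level below.

    ``confidence``: ``phi'(u_l) o (W^T (pi o e) + A^T delta)`` — the sum of
    confidence-weighted prediction errors and second-order errors.
    ``fixed``: same without the second-order pathway (``pi`` constant).
    ``classical``: ``phi'(u_l) o W^T e`` — unit confidence, first order only.

    ``_sign`` flips the second-order pathway; it exists solely so mutation
    tests can verify the gradient checker detects a wrong sign.
    """
    if level < 1 or level > state.n:
        raise IndexError(f"no bottom-up input at level {level}")
    if mode == "classical":
        return state.dphi[level] * (state.e[level - 1] @ params.W[level - 1])
    if mode == "fixed":
        return _bottom_up(params, state, level, second_order=False)
    if mode == "confidence":
        return _bottom_up(params, state, level, second_order=True, sign=_sign)
    raise ValueError(f"unknown mode {mode!r}")


def _step_directions(
    params: NetworkParams,
    state: NetworkState,
    mode: str,
) -> list[Optional[np.ndarray]]:
    """Right-hand sides ``tau du_l/dt`` per level (None where clamped)."""
    n = state.n
    rhs: list[Optional[np.ndarray]] = []
    a_mode = "fixed" if mode == "fixed" else mode
    for l in range(n + 1):
        if state.clamped[l]:
            rhs.append(None)
        elif l == 0:
            rhs.append(-state.e[0])
        elif l == n:
            rhs.append(total_propagated_error(params, state, l, a_mode))
        else:
            a = total_propagated_error(params, state, l, a_mode)
            if mode == "classical":
                rhs.append(-state.u[l] + state.mu[l] + a)
            else:
                rhs.append(-state.u[l] + state.mu[l] + a / state.pi[l])
    return rhs


def inference_step(
    params: NetworkParams,
    state: NetworkState,
    config: SimulationConfig,
    mode: str = "confidence",
) -> NetworkState:
    """One explicit Euler step of the inference dynamics.

    Unclamped levels move by ``(dt/tau) * rhs``; the returned state is fully
    consistent (rates, predictions, errors recomputed). The input state is
    not modified.
    """
    if mode == "confidence" and config.fixed_pi is not None:
        mode = "fixed"
    new_state, _ = _euler_step(params, state, config, mode)
    return new_state


def _euler_step(params, state, config, mode):
    scale = config.dt / params.tau
    rhs = _step_directions(params, state, mode)
    new_u = []
    max_du = 0.0
    for l, direction in enumerate(rhs):
        if direction is None:
            new_u.append(state.u[l])
        else:
            du = scale * direction
            max_du = max(max_du, float(np.max(np.abs(du))) if du.size else 0.0)
            new_u.append(state.u[l] + du)
    new_state = NetworkState(u=new_u, clamped=list(state.clamped))
    refresh(params, new_state, config)
    return new_state, max_du


def _classical_energy(state: NetworkState) -> float:
    """Unit-confidence quadratic energy recorded along classical runs."""
    return float(sum(0.5 * np.sum(e * e) for e in state.e))


def run_inference(
    params: NetworkParams,
    initial: NetworkState,
    config: SimulationConfig,
    mode: str = "confidence",
) -> InferenceResult:
    """Relax until the largest componentwise potential change drops below
    ``config.tol`` or ``config.max_steps`` is reached.

    Raises :class:`NumericalError` naming the step and level if any
    potential becomes non-finite. With every level clamped the initial state
    is returned immediately, converged.
    """
    config.validate(params.tau)
    if mode == "confidence" and config.fixed_pi is not None:
        mode = "fixed"
    state = refresh(params, initial, config)

    record = config.record_trajectory
    energies: list[float] = []
    level_rows: list[list[tuple[float, float]]] = []

    def _record(s: NetworkState) -> None:
        energies.append(
            _classical_energy(s) if mode == "classical" else energy(params, s)
        )
        level_rows.append(
            [
                (float(np.max(np.abs(s.e[l]))), float(np.max(np.abs(s.delta[l]))))
                for l in range(s.n)
            ]
        )

    if record:
        _record(state)

    if all(state.clamped):
        return InferenceResult(
            state, 0, True, energies, _grad_norm(params, state, mode), level_rows
        )

    converged = False
    steps = 0
    for step in range(1, config.max_steps + 1):
        state, max_du = _euler_step(params, state, config, mode)
        steps = step
        for l, u in enumerate(state.u):
            if not np.all(np.isfinite(u)):
                raise NumericalError(
                    f"non-finite potential at step {step}, level {l}"
                )
        if record:
            _record(state)
        if max_du < config.tol:
            converged = True
            break

    return InferenceResult(
        state, steps, converged, energies, _grad_norm(params, state, mode), level_rows
    )


def _grad_norm(params: NetworkParams, state: NetworkState, mode: str) -> float:
    """Max infinity-norm of the descent direction over unclamped levels."""
    rhs = _step_directions(params, state, mode)
    norms = [float(np.max(np.abs(d))) for d in rhs if d is not None and d.size]
    return max(norms, default=0.0)


def classical_pc_inference(
    params: NetworkParams,
    initial: NetworkState,
    config: SimulationConfig,
) -> InferenceResult:
    """Baseline relaxation with unit confidence and no second-order pathway.

    The scheme of classical predictive coding: representations minimise the
    Euclidean distance between inputs and point predictions, so tasks whose
    classes differ only in variance are out of its reach.
    """
    return run_inference(params, initial, config, mode="classical")


def export_trajectory(result: InferenceResult, fh: TextIO) -> None:
    """Write the recorded trajectory as delimited text.

    One row per recorded step: step index, energy, then per level
    ``max|e_l|`` and ``max|delta_l|``.
    """
    n = result.final_state.n
    cols = ["step", "energy"]
    for l in range(n):
        cols += [f"max_abs_e_{l}", f"max_abs_delta_{l}"]
    fh.write("\t".join(cols) + "\n")
    for i, en in enumerate(result.energy_trace):
        row = [str(i), f"{en:.12g}"]
        for e_max, d_max in result.level_trace[i]:
            row += [f"{e_max:.6g}", f"{d_max:.6g}"]
        fh.write("\t".join(row) + "\n")
    fh.write(
        f"# steps_taken={result.steps_taken} converged={result.converged} "
        f"max_gradient_norm={result.max_gradient_norm:.6g}\n"
    )
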