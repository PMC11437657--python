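"""Hierarchical Gaussian predictive-coding model with learned confidence.

The network is a strict generative hierarchy of ``n+1`` levels. Level 0 is
the observation; each level ``l+1`` predicts the level below through two sets
of top-down weights: ``W_l`` carries the mean of a diagonal Gaussian
predictive distribution, ``mu_l = W_l r_{l+1}``, and ``A_l`` carries its
confidence (inverse variance), ``pi_l = A_l r_{l+1}``, where
``r = phi(u)`` are the rates of the level above. The scalar energy

    E = sum_l [ 1/2 e_l^T diag(pi_l) e_l  -  1/2 sum_i log pi_{l,i} ]

with first-order prediction errors ``e_l = u_l - mu_l`` is the negative
log-joint of the hierarchical Gaussian model (up to a constant), with a
uniform prior on the top level. Its first term measures errors in units of
predicted standard deviations (a diagonal Mahalanobis distance); the second
rewards confident predictions and penalises vanishing confidence.

Alongside first-order errors the model carries second-order errors

    delta_l = (pi_l^{-1} - e_l^2) / 2,

which compare predicted uncertainty against realised squared error and
vanish in expectation exactly when the confidence is calibrated.

This module holds the parameter and state containers, the per-level algebra
(activations, predictions, errors), the energy, and its exact gradient with
respect to the membrane potentials. State arrays may carry a leading batch
axis, ``u_l`` of shape ``(batch, d_l)``; every operation broadcasts over it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger("confpc")

__version__ = "0.1.0"

#: Floor applied to every confidence component so that log(pi) and 1/pi stay
#: defined; components at the floor are treated as constants in gradients.
CONFIDENCE_FLOOR = 1e-6

#: Cap on learned confidence-weight entries; keeps the degenerate
#: zero-variance case finite.
CONFIDENCE_CAP = 1e4

ACTIVATIONS = ("rectifier", "identity", "softplus")

_identity_warned = False  # warn once per session


class ConfigurationError(ValueError):
    """Invalid configuration value (unknown name, bad shape, bad range)."""


class NumericalError(FloatingPointError):
    """Non-finite state encountered during integration."""


# ---------------------------------------------------------------------------
# Activation functions
# ---------------------------------------------------------------------------

def activation(u: np.ndarray, choice: str) -> tuple[np.ndarray, np.ndarray]:
    """Return componentwise rates ``phi(u)`` and derivative ``phi'(u)``.

    ``rectifier`` (default) and ``softplus`` output non-negative rates as the
    positivity of confidence requires; ``identity`` is a test-only mode that
    violates positivity by design.
    """
    u = np.asarray(u, dtype=float)
    if choice == "rectifier":
        return np.maximum(u, 0.0), (u > 0).astype(float)
    if choice == "identity":
        return u.copy(), np.ones_like(u)
    if choice == "softplus":
        r = np.logaddexp(0.0, u)
        dr = 0.5 * (1.0 + np.tanh(0.5 * u))  # logistic, overflow-safe
        return r, dr
    raise ConfigurationError(
        f"unknown activation {choice!r}; supported: {ACTIVATIONS}"
    )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class NetworkParams:
    """All learnable weights and fixed hyperparameters of a hierarchy.

    Attributes
    ----------
    layer_sizes:
        Dimensions ``d_0 .. d_n``; ``d_0`` is the observation dimension.
    W:
        ``n`` prediction-weight matrices, ``W_l`` of shape ``(d_l, d_{l+1})``.
    A:
        ``n`` confidence-weight matrices of the same shapes, entries > 0.
    activation:
        Name of the neuronal transfer function.
    tau:
        Membrane time constant (arbitrary units; the Euler step is ``dt/tau``).
    """

    layer_sizes: list[int]
    W: list[np.ndarray]
    A: list[np.ndarray]
    activation: str = "rectifier"
    tau: float = 1.0

    def __post_init__(self) -> None:
        self.layer_sizes = [int(d) for d in self.layer_sizes]
        self.W = [np.asarray(w, dtype=float) for w in self.W]
        self.A = [np.asarray(a, dtype=float) for a in self.A]
        if self.activation == "identity":
            global _identity_warned
            if not _identity_warned:
                _identity_warned = True
                logger.warning(
                    "identity activation selected: rates may be negative, "
                    "positivity of confidence is not guaranteed (test-only mode)"
                )
        self.validate()

    @property
    def n(self) -> int:
        """Number of prediction stages (levels minus one)."""
        return len(self.layer_sizes) - 1

    def validate(self) -> None:
        if any(d <= 0 for d in self.layer_sizes):
            raise ConfigurationError("layer sizes must be positive")
        if self.activation not in ACTIVATIONS:
            raise ConfigurationError(
                f"unknown activation {self.activation!r}; supported: {ACTIVATIONS}"
            )
        if self.tau <= 0:
            raise ConfigurationError("tau must be positive")
        n = self.n
        if len(self.W) != n or len(self.A) != n:
            raise ConfigurationError(
                f"expected {n} weight matrices per pathway, "
                f"got {len(self.W)} W and {len(self.A)} A"
            )
        for l in range(n):
            shape = (self.layer_sizes[l], self.layer_sizes[l + 1])
            if self.W[l].shape != shape:
                raise ConfigurationError(f"W[{l}] has shape {self.W[l].shape}, expected {shape}")
            if self.A[l].shape != shape:
                raise ConfigurationError(f"A[{l}] has shape {self.A[l].shape}, expected {shape}")
            if np.any(self.A[l] <= 0):
                raise ConfigurationError(f"A[{l}] has non-positive entries")

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            layer_sizes=list(self.layer_sizes),
            W=[w.copy() for w in self.W],
            A=[a.copy() for a in self.A],
            activation=self.activation,
            tau=self.tau,
        )

    # -- checkpoint serialization -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "confpc-checkpoint",
            "version": __version__,
            "layer_sizes": list(self.layer_sizes),
            "activation": self.activation,
            "tau": self.tau,
            "W": [w.tolist() for w in self.W],
            "A": [a.tolist() for a in self.A],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            layer_sizes=d["layer_sizes"],
            W=[np.asarray(w, dtype=float) for w in d["W"]],
            A=[np.asarray(a, dtype=float) for a in d["A"]],
            activation=d.get("activation", "rectifier"),
            tau=float(d.get("tau", 1.0)),
        )

    def save(self, path) -> None:
        """Write a JSON checkpoint (row-major nested arrays)."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NetworkParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def init_params(
    layer_sizes: Sequence[int],
    activation: str = "rectifier",
    tau: float = 1.0,
    seed: int = 0,
    w_scale: float = 0.1,
    a_range: tuple[float, float] = (0.5, 1.5),
) -> NetworkParams:
    """Random initial parameters.

    ``W`` entries are i.i.d. Normal(0, ``w_scale``^2); ``A`` entries are
    i.i.d. uniform on ``a_range`` — all positive, as required for the
    dynamics to descend the energy.
    """
    rng = np.random.default_rng(seed)
    sizes = list(layer_sizes)
    W = [rng.normal(0.0, w_scale, size=(sizes[l], sizes[l + 1])) for l in range(len(sizes) - 1)]
    A = [rng.uniform(*a_range, size=(sizes[l], sizes[l + 1])) for l in range(len(sizes) - 1)]
    return NetworkParams(sizes, W, A, activation=activation, tau=tau)


# ---------------------------------------------------------------------------
# Simulation configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Euler-integration settings for the inference dynamics.

    ``fixed_pi`` switches on fixed-confidence mode: confidences are held at
    the given per-level constants instead of being computed as ``A r``, and
    the second-order pathway is disabled. This diagnostic mode exposes the
    closed-form precision-weighted (Bayesian) equilibria.
    """

    dt: float = 0.05
    max_steps: int = 2000
    tol: float = 1e-6
    epsilon: float = CONFIDENCE_FLOOR
    seed: int = 0
    record_trajectory: bool = False
    fixed_pi: Optional[Sequence[np.ndarray]] = None

    def validate(self, tau: float) -> None:
        if not (0.0 < self.dt / tau <= 1.0):
            raise ConfigurationError(f"dt/tau must be in (0, 1], got {self.dt / tau}")
        if self.tol <= 0 or self.epsilon <= 0 or self.max_steps <= 0:
            raise ConfigurationError("tol, epsilon and max_steps must be positive")


# ---------------------------------------------------------------------------
# Per-level algebra
# ---------------------------------------------------------------------------

def predict(
    params: NetworkParams,
    r_above: np.ndarray,
    level: int,
    epsilon: float = CONFIDENCE_FLOOR,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-down mean and confidence sent to ``level`` by ``level+1``.

    ``mu = W_l r_above`` and ``pi = max(A_l r_above, epsilon)``; the floor
    keeps the metric positive definite when rates vanish.
    """
    r_above = np.asarray(r_above, dtype=float)
    if r_above.shape[-1] != params.layer_sizes[level + 1]:
        raise ValueError(
            f"r_above has last dimension {r_above.shape[-1]}, "
            f"expected {params.layer_sizes[level + 1]}"
        )
    mu = r_above @ params.W[level].T
    pi = np.maximum(r_above @ params.A[level].T, epsilon)
    return mu, pi


def prediction_error(u: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """First-order prediction error ``e = u - mu``."""
    u = np.asarray(u, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if u.shape != mu.shape:
        raise ValueError(f"shape mismatch: u {u.shape} vs mu {mu.shape}")
    return u - mu


def second_order_error(pi: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Second-order error ``delta = (pi^{-1} - e*e) / 2``.

    Positive when performance beats the predicted uncertainty (squared error
    below the predicted variance), negative when it falls short; zero-mean
    exactly when confidence is calibrated.
    """
    pi = np.asarray(pi, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(pi <= 0):
        raise ValueError("confidence must be strictly positive")
    return (1.0 / pi - e * e) / 2.0


# ---------------------------------------------------------------------------
# Network state
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """A consistent snapshot of the hierarchy at one time instant.

    ``u`` holds membrane potentials for levels ``0..n``; the derived arrays
    (rates, predictions, confidences, errors) are recomputed by
    :func:`refresh` whenever ``u`` changes. ``pi_floored`` marks confidence
    components held at the floor; those contribute no confidence-pathway
    gradient. ``a`` caches the total propagated error arriving at levels
    ``1..n`` (entry ``l-1`` for level ``l``) under the full dynamics.
    """

    u: list[np.ndarray]
    clamped: list[bool]
    r: list[np.ndarray] = field(default_factory=list)
    dphi: list[np.ndarray] = field(default_factory=list)
    mu: list[np.ndarray] = field(default_factory=list)
    pi: list[np.ndarray] = field(default_factory=list)
    e: list[np.ndarray] = field(default_factory=list)
    delta: list[np.ndarray] = field(default_factory=list)
    pi_floored: list[np.ndarray] = field(default_factory=list)
    a: list[np.ndarray] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.u) - 1

    def copy_potentials(self) -> list[np.ndarray]:
        return [x.copy() for x in self.u]


def make_state(
    params: NetworkParams,
    u: Sequence[np.ndarray],
    clamped: Sequence[bool],
    config: Optional[SimulationConfig] = None,
) -> NetworkState:
    """Build a consistent state from membrane potentials and clamp flags."""
    if len(u) != params.n + 1 or len(clamped) != params.n + 1:
        raise ValueError(f"need {params.n + 1} potential vectors and clamp flags")
    arrays = [np.asarray(x, dtype=float) for x in u]
    for l, x in enumerate(arrays):
        if x.shape[-1] != params.layer_sizes[l]:
            raise ValueError(
                f"u[{l}] has last dimension {x.shape[-1]}, "
                f"expected {params.layer_sizes[l]}"
            )
    state = NetworkState(u=arrays, clamped=list(clamped))
    refresh(params, state, config)
    return state


def refresh(
    params: NetworkParams,
    state: NetworkState,
    config: Optional[SimulationConfig] = None,
) -> NetworkState:
    """Recompute every derived quantity of ``state`` from its potentials."""
    cfg = config or SimulationConfig()
    n = params.n
    rates, dphis = [], []
    for l in range(n + 1):
        r, dr = activation(state.u[l], params.activation)
        rates.append(r)
        dphis.append(dr)
    state.r, state.dphi = rates, dphis

    mus, pis, es, deltas, floored = [], [], [], [], []
    for l in range(n):
        if cfg.fixed_pi is not None:
            mu = rates[l + 1] @ params.W[l].T
            pi = np.broadcast_to(
                np.asarray(cfg.fixed_pi[l], dtype=float), mu.shape
            ).copy()
            if np.any(pi <= 0):
                raise ValueError("fixed confidences must be strictly positive")
            mask = np.zeros(pi.shape, dtype=bool)
        else:
            raw = rates[l + 1] @ params.A[l].T
            mu = rates[l + 1] @ params.W[l].T
            pi = np.maximum(raw, cfg.epsilon)
            mask = raw < cfg.epsilon
        e = state.u[l] - mu
        mus.append(mu)
        pis.append(pi)
        es.append(e)
        deltas.append((1.0 / pi - e * e) / 2.0)
        floored.append(mask)
    state.mu, state.pi, state.e, state.delta, state.pi_floored = (
        mus, pis, es, deltas, floored,
    )

    # total propagated error under the full (confidence) dynamics
    second_order = cfg.fixed_pi is None
    state.a = [
        _bottom_up(params, state, l, second_order=second_order)
        for l in range(1, n + 1)
    ]
    return state


def _bottom_up(
    params: NetworkParams,
    state: NetworkState,
    level: int,
    second_order: bool = True,
    sign: float = 1.0,
) -> np.ndarray:
    """Total propagated error arriving at ``level`` from the level below.

    ``a_l = phi'(u_l) o (W_{l-1}^T (pi o e) + A_{l-1}^T delta)``; the
    second-order term is masked where the confidence floor is active and
    dropped entirely in fixed-confidence mode. ``sign`` is a test hook that
    flips the second-order pathway (used by gradient-check mutation tests).
    """
    k = level - 1
    weighted = state.pi[k] * state.e[k]
    total = weighted @ params.W[k]
    if second_order:
        delta = np.where(state.pi_floored[k], 0.0, state.delta[k])
        total = total + sign * (delta @ params.A[k])
    return state.dphi[level] * total


# ---------------------------------------------------------------------------
# Energy and its gradient
# ---------------------------------------------------------------------------

def energy(
    params: NetworkParams,
    state: NetworkState,
    aggregate: bool = True,
) -> np.ndarray:
    """Scalar energy of a consistent state.

    ``E = sum_l [ 1/2 ||e_l||^2_{pi_l} - 1/2 sum_i log pi_{l,i} ]`` — the
    negative Gaussian log-joint up to ``sum_l d_l/2 log 2 pi``. With a
    batched state the per-sample energies are summed unless
    ``aggregate=False``.
    """
    total = 0.0
    for l in range(params.n):
        pi, e = state.pi[l], state.e[l]
        if np.any(pi <= 0):
            raise ValueError("confidence must be strictly positive")
        term = 0.5 * np.sum(pi * e * e, axis=-1) - 0.5 * np.sum(np.log(pi), axis=-1)
        total = total + term
    if aggregate:
        return float(np.sum(total))
    return np.asarray(total)


def energy_gradient(params: NetworkParams, state: NetworkState, level: int) -> np.ndarray:
    """Exact gradient ``dE/du_level``.

    The local term ``pi_l o e_l`` exists below the top (the uniform top
    prior contributes none); the bottom-up term ``-a_l`` exists above the
    observation. Floored confidence components contribute no
    confidence-pathway gradient, consistent with the computed energy.
    """
    n = params.n
    if not (0 <= level <= n):
        raise IndexError(f"level {level} out of range 0..{n}")
    g = np.zeros_like(state.u[level])
    if level < n:
        g = g + state.pi[level] * state.e[level]
    if level > 0:
        g = g - _bottom_up(params, state, level, second_order=True)
    return g
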