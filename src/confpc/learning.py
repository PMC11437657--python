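"""Local synaptic learning rules and the supervised training loop.

At the equilibrium of the inference dynamics, both weight pathways descend
the same energy that drives inference:

* prediction weights follow the classical predictive-coding rule
  ``dW_l ∝ (pi_l o e_l) r_{l+1}^T`` — presynaptic rates times postsynaptic
  confidence-weighted errors, so confident wrong predictions learn fastest;

* confidence weights follow ``dA_l ∝ delta_l r_{l+1}^T`` — presynaptic
  rates times postsynaptic second-order errors, driving ``pi`` toward the
  inverse variance of the residual errors.

Because ``pi = A r`` enters the energy as a metric it must stay positive.
The multiplicative variant ``dA_l ∝ A_l o (delta_l r_{l+1}^T)`` modulates
the learning rate by the current weight, preventing zero crossings in
continuous time; a per-entry step-factor guard extends that guarantee to
discrete steps, and it is the default. The plain rule is kept for
gradient-equivalence checks and clips at the confidence floor if it ever
undershoots.

Training is supervised in the generative sense: the observation level is
clamped to the data vector and the top level to a one-hot target, hidden
levels (if any) relax to equilibrium, then each pathway takes one step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    CONFIDENCE_CAP,
    CONFIDENCE_FLOOR,
    ConfigurationError,
    NetworkParams,
    NetworkState,
    SimulationConfig,
    make_state,
)
from .dynamics import run_inference

logger = logging.getLogger("confpc")

__all__ = ["LearningConfig", "TrainReport", "update_W", "update_A", "train_supervised"]

#: Bounds on the per-entry multiplicative step factor 1 + lr*delta*r; keeps
#: single discrete steps from flipping sign or more than halving/1.5x-ing
#: a confidence weight.
STEP_FACTOR_BOUNDS = (0.5, 1.5)

A_RULES = ("plain", "multiplicative")


@dataclass
class LearningConfig:
    """Learning rates, rule choice and schedule for supervised training."""

    lr_W: float = 0.01
    lr_A: float = 0.005
    a_rule: str = "multiplicative"
    epochs: int = 30
    shuffle_seed: int = 0
    inference: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.lr_W <= 0 or self.lr_A <= 0:
            raise ConfigurationError("learning rates must be positive")
        if self.a_rule not in A_RULES:
            raise ConfigurationError(f"a_rule must be one of {A_RULES}")
        if self.epochs < 0:
            raise ConfigurationError("epochs must be non-negative")


@dataclass
class TrainReport:
    """Per-epoch training diagnostics."""

    mean_energy: list[float] = field(default_factory=list)
    mean_abs_e: list[float] = field(default_factory=list)
    mean_abs_delta: list[float] = field(default_factory=list)
    accuracy: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "epoch": np.arange(len(self.mean_energy)),
                "mean_energy": self.mean_energy,
                "mean_abs_e": self.mean_abs_e,
                "mean_abs_delta": self.mean_abs_delta,
            }
        )
        if self.accuracy is not None:
            df["accuracy"] = self.accuracy
        return df

    def save(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def update_W(params: NetworkParams, state: NetworkState, lr_W: float) -> NetworkParams:
    """One gradient step on every prediction-weight matrix.

    ``W_l <- W_l + lr_W (pi_l o e_l) r_{l+1}^T``; confidence weights are
    untouched. Expects a consistent single-sample (unbatched) state at
    approximate equilibrium.
    """
    out = params.copy()
    for l in range(params.n):
        post = state.pi[l] * state.e[l]
        if post.ndim != 1:
            raise ValueError("weight updates require an unbatched state")
        out.W[l] += lr_W * np.outer(post, state.r[l + 1])
    return out


def update_A(
    params: NetworkParams,
    state: NetworkState,
    lr_A: float,
    a_rule: str = "multiplicative",
) -> NetworkParams:
    """One gradient step on every confidence-weight matrix.

    ``plain``: ``A_l <- A_l + lr_A delta_l r_{l+1}^T``, clipping any entry
    driven below the confidence floor (with a warning) — the raw gradient
    carries no positivity guarantee.

    ``multiplicative``: ``A_l <- A_l + lr_A A_l o (delta_l r_{l+1}^T)``,
    with the per-entry factor ``1 + lr_A delta r`` clipped to
    ``STEP_FACTOR_BOUNDS``, so entries provably stay positive for any step.

    Entries are capped at :data:`confpc.model.CONFIDENCE_CAP` so degenerate
    zero-variance data cannot push confidence to infinity.
    """
    if a_rule not in A_RULES:
        raise ConfigurationError(f"a_rule must be one of {A_RULES}")
    out = params.copy()
    for l in range(params.n):
        delta = state.delta[l]
        if delta.ndim != 1:
            raise ValueError("weight updates require an unbatched state")
        outer = np.outer(delta, state.r[l + 1])
        if a_rule == "plain":
            new = out.A[l] + lr_A * outer
            low = new < CONFIDENCE_FLOOR
            if np.any(low):
                logger.warning(
                    "plain confidence rule drove %d entries of A[%d] to the "
                    "floor; clipped",
                    int(np.sum(low)),
                    l,
                )
                new = np.where(low, CONFIDENCE_FLOOR, new)
        else:
            factor = np.clip(1.0 + lr_A * outer, *STEP_FACTOR_BOUNDS)
            new = out.A[l] * factor
        capped = new > CONFIDENCE_CAP
        if np.any(capped):
            logger.warning(
                "confidence cap %.3g hit by %d entries of A[%d]",
                CONFIDENCE_CAP,
                int(np.sum(capped)),
                l,
            )
            new = np.where(capped, CONFIDENCE_CAP, new)
        out.A[l] = new
    return out


def _sample_arrays(item) -> tuple[np.ndarray, np.ndarray]:
    """Accept LabelledSample-like objects or (x, one_hot) pairs."""
    if hasattr(item, "x") and hasattr(item, "one_hot"):
        return np.asarray(item.x, float), np.asarray(item.one_hot, float)
    x, t = item
    return np.asarray(x, float), np.asarray(t, float)


def train_supervised(
    params: NetworkParams,
    dataset: Sequence,
    lcfg: LearningConfig,
) -> tuple[NetworkParams, TrainReport]:
    """Online supervised training with clamped observation and target.

    Per sample (shuffled each epoch): clamp level 0 to the data vector and
    level ``n`` to the one-hot target, relax any hidden levels to
    equilibrium, then apply one prediction-weight and one confidence-weight
    update. A two-level network has no hidden levels, so its inner loop is
    pure learning. Returns the trained parameters and per-epoch means of
    energy, ``|e|`` and ``|delta|``.
    """
    lcfg.validate()
    cfg = lcfg.inference
    n = params.n
    rng = np.random.default_rng(lcfg.shuffle_seed)
    items = [_sample_arrays(it) for it in dataset]
    if items and items[0][1].shape[-1] != params.layer_sizes[n]:
        raise ValueError(
            f"label dimension {items[0][1].shape[-1]} does not match "
            f"top layer size {params.layer_sizes[n]}"
        )
    if items and items[0][0].shape[-1] != params.layer_sizes[0]:
        raise ValueError(
            f"data dimension {items[0][0].shape[-1]} does not match "
            f"observation size {params.layer_sizes[0]}"
        )

    report = TrainReport()
    params = params.copy()
    from .model import energy as _energy  # local alias

    for _epoch in range(lcfg.epochs):
        order = rng.permutation(len(items))
        e_sum = d_sum = en_sum = 0.0
        e_cnt = d_cnt = 0
        for idx in order:
            x, target = items[idx]
            u = [x]
            for l in range(1, n):
                u.append(np.full(params.layer_sizes[l], 0.5))
            u.append(target)
            clamped = [True] + [False] * (n - 1) + [True]
            state = make_state(params, u, clamped, cfg)
            if n > 1:  # relax hidden levels to equilibrium first
                state = run_inference(params, state, cfg).final_state
            params = update_W(params, state, lcfg.lr_W)
            params = update_A(params, state, lcfg.lr_A, lcfg.a_rule)
            # diagnostics from the pre-update state
            en_sum += _energy(params, state)
            for l in range(n):
                e_sum += float(np.sum(np.abs(state.e[l])))
                d_sum += float(np.sum(np.abs(state.delta[l])))
                e_cnt += state.e[l].size
                d_cnt += state.delta[l].size
        m = max(len(items), 1)
        report.mean_energy.append(en_sum / m)
        report.mean_abs_e.append(e_sum / max(e_cnt, 1))
        report.mean_abs_delta.append(d_sum / max(d_cnt, 1))
    return params, report
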