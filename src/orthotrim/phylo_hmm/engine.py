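"""Generic discrete-state HMM: forward/backward with posterior decoding.

The engine is decoupled from the emission layer through a small contract:
an emission handle exposes ``log_matrix(observations) -> (T, S)`` giving
per-position, per-state emission log-probabilities.  Observations are
otherwise opaque to the engine.  Numerical stability comes from
per-position scaling constants rather than log-space recursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

__all__ = ["EmissionHandle", "TableEmission", "HMMSpec", "ForwardBackwardResult", "forward_backward"]


class EmissionHandle(Protocol):
    def log_matrix(self, observations) -> np.ndarray: ...


@dataclass
class TableEmission:
    """Categorical emissions from a (states x symbols) probability table."""

    table: np.ndarray

    def log_matrix(self, observations) -> np.ndarray:
        obs = np.asarray(observations, dtype=int)
        with np.errstate(divide="ignore"):
            return np.log(self.table[:, obs]).T


@dataclass
class HMMSpec:
    """States, start distribution, transition matrix, and emission handle."""

    states: list[str]
    start: np.ndarray
    trans: np.ndarray
    emission: EmissionHandle

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        n = len(self.states)
        if self.start.shape != (n,) or self.trans.shape != (n, n):
            raise ValueError("distribution shapes do not match state count")
        if abs(self.start.sum() - 1.0) > 1e-9:
            raise ValueError("start distribution must sum to 1")
        if np.any(np.abs(self.trans.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class ForwardBackwardResult:
    posteriors: np.ndarray  # (T, S), rows sum to 1
    log_likelihood: float
    forward: np.ndarray = field(repr=False)
    backward: np.ndarray = field(repr=False)


def forward_backward(spec: HMMSpec, observations) -> ForwardBackwardResult:
    """Scaled forward/backward recursions with posterior decoding.

    Raises ``ValueError`` (with the offending position) when every state
    assigns zero probability to some observation.
    """
    log_e = np.asarray(spec.emission.log_matrix(observations), dtype=float)
    if log_e.ndim != 2 or log_e.shape[1] != spec.n_states:
        raise ValueError("emission matrix shape mismatch")
    t_len = log_e.shape[0]
    if t_len == 0:
        return ForwardBackwardResult(
            posteriors=np.zeros((0, spec.n_states)),
            log_likelihood=0.0,
            forward=np.zeros((0, spec.n_states)),
            backward=np.zeros((0, spec.n_states)),
        )
    shift = log_e.max(axis=1)
    if not np.all(np.isfinite(shift)):
        bad = int(np.flatnonzero(~np.isfinite(shift))[0])
        raise ValueError(f"all-zero emission column at position {bad}")
    e = np.exp(log_e - shift[:, None])

    alpha = np.empty((t_len, spec.n_states))
    scale = np.empty(t_len)
    alpha[0] = spec.start * e[0]
    scale[0] = alpha[0].sum()
    if scale[0] <= 0:
        raise ValueError("all-zero emission column at position 0")
    alpha[0] /= scale[0]
    for t in range(1, t_len):
        alpha[t] = (alpha[t - 1] @ spec.trans) * e[t]
        scale[t] = alpha[t].sum()
        if scale[t] <= 0:
            raise ValueError(f"all-zero emission column at position {t}")
        alpha[t] /= scale[t]

    beta = np.empty((t_len, spec.n_states))
    beta[-1] = 1.0
    for t in range(t_len - 2, -1, -1):
        beta[t] = (spec.trans @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    posteriors = alpha * beta
    posteriors /= posteriors.sum(axis=1, keepdims=True)
    log_likelihood = float(np.log(scale).sum() + shift.sum())
    return ForwardBackwardResult(
        posteriors=posteriors,
        log_likelihood=log_likelihood,
        forward=alpha,
        backward=beta,
    )
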