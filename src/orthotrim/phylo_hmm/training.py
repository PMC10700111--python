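"""Discriminative training of the phylogenetic HMM.

The objective is the mean per-position cross-entropy between the
posterior decoding and the supplied state labels, minimized over
unconstrained reparameterizations: logits for the start and transition
distributions, log-rates for the CTMC, logits for the tip-jump mixture,
and log-shapes for the stickiness component.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .emission import BinaryCTMC, EmissionParams, PhyloEmission, StickinessParams, TipJump
from .engine import HMMSpec, forward_backward

__all__ = ["TrainResult", "train_discriminative"]

_CLIP = 30.0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))

def _logit(p: float) -> float:
    p = min(max(p, 1e-10), 1 - 1e-10)
    return float(np.log(p / (1 - p)))

def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()

def _safe_log(x: float) -> float:
    return float(np.log(max(x, 1e-12)))


def _pack(spec: HMMSpec) -> np.ndarray:
    n = spec.n_states
    parts = [np.log(np.maximum(spec.start, 1e-12)), np.log(np.maximum(spec.trans, 1e-12)).ravel()]
    for p in spec.emission.params:
        parts.append(
            np.array(
                [
                    _safe_log(p.ctmc.rate_gain),
                    _safe_log(p.ctmc.rate_loss),
                    _logit(p.jump.epsilon),
                    _logit(p.jump.q),
                    _safe_log(p.stickiness.a),
                    _safe_log(p.stickiness.b),
                ]
            )
        )
    return np.concatenate(parts)


def _unpack(vector: np.ndarray, template: HMMSpec) -> HMMSpec:
    n = template.n_states
    pos = 0
    start = _softmax(vector[pos : pos + n]); pos += n
    trans = np.empty((n, n))
    for i in range(n):
        trans[i] = _softmax(vector[pos : pos + n]); pos += n
    params = []
    for _ in range(n):
        chunk = vector[pos : pos + 6]; pos += 6
        params.append(
            EmissionParams(
                ctmc=BinaryCTMC(
                    float(np.exp(np.clip(chunk[0], -_CLIP, _CLIP))),
                    float(np.exp(np.clip(chunk[1], -_CLIP, _CLIP))),
                ),
                jump=TipJump(float(_sigmoid(chunk[2])), float(_sigmoid(chunk[3]))),
                stickiness=StickinessParams(
                    float(np.exp(np.clip(chunk[4], -_CLIP, _CLIP))),
                    float(np.exp(np.clip(chunk[5], -_CLIP, _CLIP))),
                ),
            )
        )
    emission = PhyloEmission(template.emission.tree, params)
    return HMMSpec(list(template.states), start, trans, emission)


def _cross_entropy(spec: HMMSpec, labeled: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    total, count = 0.0, 0
    for observations, labels in labeled:
        result = forward_backward(spec, observations)
        p = result.posteriors[np.arange(len(labels)), labels]
        total -= float(np.log(np.maximum(p, 1e-300)).sum())
        count += len(labels)
    loss = total / max(count, 1)
    if not np.isfinite(loss):
        raise ValueError("non-finite training loss")
    return loss


@dataclass
class TrainResult:
    spec: HMMSpec
    history: list[float]  # loss at init plus each improving iterate

    @property
    def final_loss(self) -> float:
        return self.history[-1]


def train_discriminative(
    spec0: HMMSpec,
    labeled: Sequence[tuple[np.ndarray, np.ndarray]],
    maxiter: int = 50,
) -> TrainResult:
    """Minimize posterior cross-entropy against labels.

    ``labeled`` is a sequence of (observations, labels) pairs where the
    observations feed the spec's emission handle and labels are integer
    state indices per position.  Returns the trained spec when it improves
    on ``spec0`` and ``spec0`` itself otherwise; the history records the
    initial loss followed by each improving iterate (monotone by
    construction).
    """
    for _, labels in labeled:
        if len(labels) == 0:
            raise ValueError("empty labeled sequence")
    x0 = _pack(spec0)
    loss0 = _cross_entropy(spec0, labeled)
    history = [loss0]
    best = {"x": x0.copy(), "loss": loss0}

    def objective(x: np.ndarray) -> float:
        return _cross_entropy(_unpack(x, spec0), labeled)

    def callback(x: np.ndarray) -> None:
        loss = objective(x)
        if loss < best["loss"]:
            best["loss"] = loss
            best["x"] = x.copy()
            history.append(loss)

    minimize(
        objective,
        x0,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": maxiter, "eps": 1e-5},
    )
    if best["loss"] < loss0:
        return TrainResult(spec=_unpack(best["x"], spec0), history=history)
    return TrainResult(spec=spec0, history=history)
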