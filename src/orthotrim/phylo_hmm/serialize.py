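"""Flat key-value serialization of model parameters.

One row per parameter: ``state <TAB> component <TAB> parameter <TAB>
value``.  Start and transition entries use the pseudo-components
``start`` and ``trans``.
"""

from __future__ import annotations

import csv

import numpy as np

from .emission import BinaryCTMC, EmissionParams, StickinessParams, TipJump

__all__ = ["write_params", "read_params"]


def write_params(path, spec) -> None:
    rows: list[tuple[str, str, str, float]] = []
    for i, state in enumerate(spec.states):
        rows.append((state, "start", "p", float(spec.start[i])))
        for j, other in enumerate(spec.states):
            rows.append((state, "trans", other, float(spec.trans[i, j])))
        p = spec.emission.params[i]
        rows.extend(
            [
                (state, "ctmc", "rate_gain", p.ctmc.rate_gain),
                (state, "ctmc", "rate_loss", p.ctmc.rate_loss),
                (state, "jump", "epsilon", p.jump.epsilon),
                (state, "jump", "q", p.jump.q),
                (state, "stickiness", "a", p.stickiness.a),
                (state, "stickiness", "b", p.stickiness.b),
            ]
        )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["state", "component", "parameter", "value"])
        for row in rows:
            writer.writerow([row[0], row[1], row[2], repr(row[3])])


def read_params(path) -> tuple[list[str], np.ndarray, np.ndarray, list[EmissionParams]]:
    """Read back (states, start, trans, emission params)."""
    entries: dict[tuple[str, str, str], float] = {}
    states: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:4] != ["state", "component", "parameter", "value"]:
            raise ValueError("unrecognized parameter file header")
        for state, component, parameter, value in reader:
            if state not in states:
                states.append(state)
            entries[(state, component, parameter)] = float(value)
    n = len(states)
    start = np.array([entries[(s, "start", "p")] for s in states])
    trans = np.array([[entries[(s, "trans", t)] for t in states] for s in states])
    params = [
        EmissionParams(
            ctmc=BinaryCTMC(entries[(s, "ctmc", "rate_gain")], entries[(s, "ctmc", "rate_loss")]),
            jump=TipJump(entries[(s, "jump", "epsilon")], entries[(s, "jump", "q")]),
            stickiness=StickinessParams(
                entries[(s, "stickiness", "a")], entries[(s, "stickiness", "b")]
            ),
        )
        for s in states
    ]
    return states, start, trans, params
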