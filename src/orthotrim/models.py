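"""Default curation model parameters.

These four insertion states correspond to: strongly supported columns
(two flavors, one near-gapless and one moderately gappy), stable gap
patterns discordant with the tree (skipped exons), and poorly supported
segments present in very few sequences.  The missing-data model has a
"not missing" state tracking the phylogenetic consensus and a "missing"
state dominated by tip-level annotation noise toward gaps.
"""

from __future__ import annotations

import numpy as np

from .phylo_hmm import (
    BinaryCTMC,
    EmissionParams,
    HMMSpec,
    MissingEmission,
    PhyloEmission,
    StickinessParams,
    TipJump,
)
from .trees import ArrayTree

__all__ = [
    "INSERTION_STATES",
    "STATE2_INDEX",
    "STATE3_INDEX",
    "MISSING_STATES",
    "MISSING_INDEX",
    "default_insertion_params",
    "default_missing_params",
    "insertion_spec",
    "missing_spec_factory",
]

INSERTION_STATES = ["1A", "1B", "2", "3"]
STATE2_INDEX = 2
STATE3_INDEX = 3

MISSING_STATES = ["not_missing", "missing"]
MISSING_INDEX = 1


def default_insertion_params() -> list[EmissionParams]:
    return [
        # 1A: near-gapless, phylogenetically coherent, very sticky
        EmissionParams(
            BinaryCTMC(rate_gain=4.0, rate_loss=0.2),
            TipJump(epsilon=0.05, q=0.9),
            StickinessParams(a=10.0, b=1.0),
        ),
        # 1B: moderately gappy but still tree-concordant
        EmissionParams(
            BinaryCTMC(rate_gain=1.0, rate_loss=1.0),
            TipJump(epsilon=0.1, q=0.5),
            StickinessParams(a=5.0, b=2.0),
        ),
        # 2: stable gap pattern discordant with the tree (low rates, so
        # tip patterns persist; the jump mixture carries the discordance)
        EmissionParams(
            BinaryCTMC(rate_gain=0.05, rate_loss=0.05),
            TipJump(epsilon=0.5, q=0.5),
            StickinessParams(a=20.0, b=1.0),
        ),
        # 3: poorly supported segments: most tips gap, tips independent
        EmissionParams(
            BinaryCTMC(rate_gain=8.0, rate_loss=72.0),
            TipJump(epsilon=0.1, q=0.1),
            StickinessParams(a=8.0, b=2.0),
        ),
    ]


def default_insertion_trans() -> tuple[np.ndarray, np.ndarray]:
    start = np.array([0.7, 0.1, 0.1, 0.1])
    trans = np.array(
        [
            [0.96, 0.02, 0.01, 0.01],
            [0.06, 0.90, 0.02, 0.02],
            [0.04, 0.02, 0.92, 0.02],
            [0.04, 0.02, 0.02, 0.92],
        ]
    )
    return start, trans


def insertion_spec(tree: ArrayTree, params: list[EmissionParams] | None = None) -> HMMSpec:
    start, trans = default_insertion_trans()
    emission = PhyloEmission(tree, params or default_insertion_params())
    return HMMSpec(list(INSERTION_STATES), start, trans, emission)


def default_missing_params() -> list[EmissionParams]:
    return [
        # not missing: the focal tip follows the consensus of the others
        EmissionParams(
            BinaryCTMC(rate_gain=1.0, rate_loss=0.5),
            TipJump(epsilon=0.05, q=0.5),
            StickinessParams(a=1.0, b=1.0),
        ),
        # missing: the focal tip is gap regardless of the others
        EmissionParams(
            BinaryCTMC(rate_gain=1.0, rate_loss=0.5),
            TipJump(epsilon=0.95, q=0.05),
            StickinessParams(a=1.0, b=1.0),
        ),
    ]


def missing_spec_factory(tree: ArrayTree, params: list[EmissionParams] | None = None):
    params = params or default_missing_params()
    start = np.array([0.95, 0.05])
    trans = np.array([[0.99, 0.01], [0.02, 0.98]])

    def factory(focal_species: str) -> HMMSpec:
        emission = MissingEmission(tree, params, focal_species)
        return HMMSpec(list(MISSING_STATES), start, trans, emission)

    return factory
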