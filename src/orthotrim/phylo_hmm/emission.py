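"""Phylogenetic emission models for binary gap characters.

Each hidden state carries a 2-state CTMC evolved along the species tree,
an observation-error ("jump") mixture at the tips, and a beta-Bernoulli
"gap stickiness" component on the number of tip symbols constant between
subsequent columns.  Column symbols are coded 0 = gap, 1 = non-gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import betabinom

from ..trees import ArrayTree

__all__ = [
    "BinaryCTMC",
    "TipJump",
    "StickinessParams",
    "EmissionParams",
    "PhyloEmission",
    "MissingEmission",
    "prune_likelihood",
    "prune_loglik_columns",
    "column_emission",
    "missing_emission",
    "simulate",
]


@dataclass(frozen=True)
class BinaryCTMC:
    """Two-state CTMC with rates gap->non-gap and non-gap->gap."""

    rate_gain: float  # gap -> non-gap
    rate_loss: float  # non-gap -> gap

    def __post_init__(self) -> None:
        if self.rate_gain < 0 or self.rate_loss < 0:
            raise ValueError("rates must be non-negative")

    @property
    def stationary(self) -> np.ndarray:
        s = self.rate_gain + self.rate_loss
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([self.rate_loss / s, self.rate_gain / s])

    def transition(self, t: float) -> np.ndarray:
        """exp(Q t) in closed form for the 2-state generator."""
        if t < 0:
            raise ValueError("negative branch length")
        s = self.rate_gain + self.rate_loss
        if s == 0:
            return np.eye(2)
        pi = self.stationary
        decay = np.exp(-s * t)
        return pi[None, :] + decay * (np.eye(2) - pi[None, :])


@dataclass(frozen=True)
class TipJump:
    """Observation-error mixture at the tips.

    With probability ``epsilon`` the observed tip symbol is redrawn from a
    Bernoulli with non-gap probability ``q`` instead of reflecting the
    CTMC state.
    """

    epsilon: float
    q: float

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon <= 1 and 0 <= self.q <= 1):
            raise ValueError("epsilon and q must lie in [0, 1]")


@dataclass(frozen=True)
class StickinessParams:
    """Beta shape parameters of the beta-binomial stickiness component."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("beta shapes must be positive")


@dataclass(frozen=True)
class EmissionParams:
    ctmc: BinaryCTMC
    jump: TipJump
    stickiness: StickinessParams


# ----------------------------------------------------------------------
# pruning
# ----------------------------------------------------------------------
def _tip_partials(obs: np.ndarray, jump: TipJump) -> np.ndarray:
    """(T, 2) partial likelihoods at one tip for observed symbols ``obs``."""
    bern = np.where(obs == 1, jump.q, 1.0 - jump.q)
    partial = np.empty((obs.shape[0], 2))
    for x in (0, 1):
        partial[:, x] = (1.0 - jump.epsilon) * (obs == x) + jump.epsilon * bern
    return partial


def prune_loglik_columns(
    tree: ArrayTree,
    ctmc: BinaryCTMC,
    jump: TipJump,
    columns: np.ndarray,
) -> np.ndarray:
    """Column log-likelihoods by vectorized post-order pruning.

    ``columns`` has shape (n_tips, T) over {0, 1}, rows ordered as
    ``tree.tip_labels``.
    """
    columns = np.asarray(columns)
    if columns.shape[0] != tree.n_tips:
        raise ValueError("column row count does not match tree tips")
    t_len = columns.shape[1]
    tip_pos = {int(node): j for j, node in enumerate(tree.tip_index)}
    branch_p = [ctmc.transition(float(bl)) for bl in tree.edge_length]
    partials: list[np.ndarray | None] = [None] * tree.n_nodes
    for i in range(tree.n_nodes):  # post-order by construction
        kids = tree.children[i]
        if not kids:
            partials[i] = _tip_partials(columns[tip_pos[i]], jump)
        else:
            acc = np.ones((t_len, 2))
            for c in kids:
                acc *= partials[c] @ branch_p[c].T
                partials[c] = None
            partials[i] = acc
    root = partials[tree.n_nodes - 1]
    lik = root @ ctmc.stationary
    with np.errstate(divide="ignore"):
        return np.log(lik)


def prune_likelihood(
    tree: ArrayTree,
    ctmc: BinaryCTMC,
    jump: TipJump,
    column: dict[str, int],
) -> float:
    """Likelihood of a single column given as a tip-label -> symbol map."""
    obs = np.array([[column[label]] for label in tree.tip_labels])
    return float(np.exp(prune_loglik_columns(tree, ctmc, jump, obs)[0]))


# ----------------------------------------------------------------------
# column emission (insertion model)
# ----------------------------------------------------------------------
def column_emission(
    params: EmissionParams,
    tree: ArrayTree,
    column: dict[str, int],
    prev_column: dict[str, int] | None,
    n_tips: int | None = None,
) -> float:
    """Log emission: pruning term plus the beta-binomial stickiness term.

    The stickiness term counts tips whose symbol is unchanged from the
    previous column; the first column (no predecessor) omits it.
    """
    n = n_tips if n_tips is not None else tree.n_tips
    logp = np.log(prune_likelihood(tree, params.ctmc, params.jump, column))
    if prev_column is not None:
        c = sum(int(column[t] == prev_column[t]) for t in tree.tip_labels)
        logp += float(betabinom.logpmf(c, n, params.stickiness.a, params.stickiness.b))
    return float(logp)


class PhyloEmission:
    """Per-state phylogenetic emission handle for the HMM engine.

    Observations are a (n_tips, T) matrix of column symbols; the log
    matrix combines the pruning likelihood of each column with the
    stickiness term on subsequent-column constancy.
    """

    def __init__(self, tree: ArrayTree, params: Sequence[EmissionParams]) -> None:
        self.tree = tree
        self.params = list(params)

    @property
    def n_states(self) -> int:
        return len(self.params)

    def log_matrix(self, observations: np.ndarray) -> np.ndarray:
        columns = np.asarray(observations)
        t_len = columns.shape[1]
        n = self.tree.n_tips
        out = np.empty((t_len, self.n_states))
        constant = None
        if t_len > 1:
            constant = (columns[:, 1:] == columns[:, :-1]).sum(axis=0)
        for s, p in enumerate(self.params):
            out[:, s] = prune_loglik_columns(self.tree, p.ctmc, p.jump, columns)
            if constant is not None:
                out[1:, s] += betabinom.logpmf(constant, n, p.stickiness.a, p.stickiness.b)
        return out


# ----------------------------------------------------------------------
# missing-data emission
# ----------------------------------------------------------------------
def _posterior_of_observed(
    tree: ArrayTree,
    ctmc: BinaryCTMC,
    jump: TipJump,
    columns: np.ndarray,
    focal: int,
) -> np.ndarray:
    """P(observed symbol at focal tip | symbols at all other tips), per column."""
    obs = prune_loglik_columns(tree, ctmc, jump, columns)
    flipped = columns.copy()
    flipped[focal] = 1 - flipped[focal]
    alt = prune_loglik_columns(tree, ctmc, jump, flipped)
    m = np.maximum(obs, alt)
    return np.exp(obs - m) / (np.exp(obs - m) + np.exp(alt - m))


def missing_emission(
    tree: ArrayTree,
    ctmc: BinaryCTMC,
    jump: TipJump,
    column: dict[str, int],
    focal_tip: str,
) -> float:
    """Posterior probability of the focal tip's observed symbol."""
    focal = tree.tip_labels.index(focal_tip)
    obs = np.array([[column[label]] for label in tree.tip_labels])
    return float(_posterior_of_observed(tree, ctmc, jump, obs, focal)[0])


class MissingEmission:
    """Per-state emission for the missing-data model.

    Each position of the focal sequence emits the posterior probability of
    its observed symbol given the other tips, under the state's process.
    """

    def __init__(
        self,
        tree: ArrayTree,
        params: Sequence[EmissionParams],
        focal_tip: str,
    ) -> None:
        self.tree = tree
        self.params = list(params)
        self.focal = tree.tip_labels.index(focal_tip)

    def log_matrix(self, observations: np.ndarray) -> np.ndarray:
        columns = np.asarray(observations)
        out = np.empty((columns.shape[1], len(self.params)))
        for s, p in enumerate(self.params):
            post = _posterior_of_observed(self.tree, p.ctmc, p.jump, columns, self.focal)
            with np.errstate(divide="ignore"):
                out[:, s] = np.log(post)
        return out


# ----------------------------------------------------------------------
# simulation
# ----------------------------------------------------------------------
def simulate(
    spec,
    tree: ArrayTree,
    length: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and tip columns from the generative model.

    The stickiness component is not separately sampled — columns are
    drawn from each state's phylogenetic process only, so stickiness is
    emergent from the CTMC correlation structure.  Returns (path,
    columns) with columns shaped (n_tips, length).
    """
    rng = np.random.default_rng(seed)
    n_states = spec.n_states
    path = np.empty(length, dtype=int)
    if length == 0:
        return path, np.zeros((tree.n_tips, 0), dtype=int)
    path[0] = rng.choice(n_states, p=spec.start)
    for t in range(1, length):
        path[t] = rng.choice(n_states, p=spec.trans[path[t - 1]])

    params = spec.emission.params
    columns = np.zeros((tree.n_tips, length), dtype=int)
    tip_pos = {int(node): j for j, node in enumerate(tree.tip_index)}
    for s in range(n_states):
        idx = np.flatnonzero(path == s)
        if idx.size == 0:
            continue
        p = params[s]
        branch_p = [p.ctmc.transition(float(bl)) for bl in tree.edge_length]
        state_at: list[np.ndarray | None] = [None] * tree.n_nodes
        root = tree.n_nodes - 1
        state_at[root] = (rng.random(idx.size) < p.ctmc.stationary[1]).astype(int)
        for i in range(tree.n_nodes - 1, -1, -1):  # pre-order (parents first)
            for c in tree.children[i]:
                p_gain = branch_p[c][state_at[i], 1]
                state_at[c] = (rng.random(idx.size) < p_gain).astype(int)
        for node, j in tip_pos.items():
            obs = state_at[node].copy()
            jump_mask = rng.random(idx.size) < p.jump.epsilon
            obs[jump_mask] = (rng.random(jump_mask.sum()) < p.jump.q).astype(int)
            columns[j, idx] = obs
    return path, columns
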