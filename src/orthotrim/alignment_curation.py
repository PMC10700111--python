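"""Posterior-driven alignment trimming and missing-segment calls.

State-3 (poorly supported) regions are trimmed per sequence with a
geometric-model cutoff on the number of non-gap symbols; residual state-2
(phylogenetically discordant) regions are trimmed per column; the
missing-data model's posteriors are converted into per-sequence gap
segments reported as slice lists.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

from .profile_weighting import BinaryAlignment, SpeciesWeights, gap_profile

__all__ = [
    "RegionCall",
    "TrimAction",
    "geometric_cutoff",
    "define_regions",
    "trim_state3",
    "trim_state2",
    "call_missing",
    "apply_trims",
    "format_segments",
]

STATE3_HIGH = 0.75
STATE3_LOW = 1e-3
STATE3_DERIV = 0.001
STATE2_HIGH = 0.9
STATE3_MASK_CUT = 0.1
MISSING_SEED = 0.75
MISSING_STOP = 0.05


@dataclass(frozen=True)
class RegionCall:
    start: int
    stop: int
    state: int
    seed_start: int
    seed_stop: int

    def __post_init__(self) -> None:
        if not (self.start <= self.seed_start < self.seed_stop <= self.stop):
            raise ValueError("seed must lie within the region")


@dataclass(frozen=True)
class TrimAction:
    kind: str  # "segment" | "column" | "missing"
    start: int
    stop: int
    sequence_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("segment", "column", "missing"):
            raise ValueError(f"bad trim kind {self.kind!r}")
        if self.kind != "column" and self.sequence_id is None:
            raise ValueError("segment/missing trims need a sequence id")


def geometric_cutoff(mu: float, alpha: float = 0.01) -> float:
    """k = log(alpha) / log(1 - p) - 1 with p = 1 / (mu + 1).

    mu -> 0 gives k -> -1 (every sequence with any non-gap symbol trims).
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu == 0:
        return -1.0
    p = 1.0 / (mu + 1.0)
    return math.log(alpha) / math.log(1.0 - p) - 1.0


# ----------------------------------------------------------------------
# region definition
# ----------------------------------------------------------------------
def _seed_runs(prob: np.ndarray, high_cut: float) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, v in enumerate(prob >= high_cut):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, prob.size))
    return runs


def _boundary(
    window_lo: int,
    window_hi: int,
    deriv: np.ndarray,
    gap_step: np.ndarray,
) -> int:
    """Column index maximizing |derivative| x |gap-profile change|.

    The boundary sits *after* the maximizing step, i.e. at index + 1;
    ties resolve to the smallest index.
    """
    lo = max(window_lo, 0)
    hi = min(window_hi, deriv.size - 1)
    if hi < lo:
        return window_lo + 1
    window = np.abs(deriv[lo : hi + 1]) * np.abs(gap_step[lo : hi + 1])
    return lo + int(np.argmax(window)) + 1


def define_regions(
    prob: np.ndarray,
    gap_prof: np.ndarray,
    high_cut: float,
    low_cut: float,
    d_out: float,
    d_in: float,
    state: int = 3,
) -> list[RegionCall]:
    """Seed-and-expand region calls from a per-column state posterior.

    Seeds are maximal runs with prob >= high_cut.  Each seed endpoint
    expands outward while the probability stays >= low_cut and the
    absolute derivative stays >= d_out, and inward while the absolute
    derivative stays >= d_in; the boundary within each window is the
    column after the step maximizing |derivative| x |gap-profile change|.
    Overlapping or adjacent regions are merged (their seeds unioned).
    """
    if low_cut > high_cut:
        raise ValueError("low cutoff exceeds high cutoff")
    prob = np.asarray(prob, dtype=float)
    gap_prof = np.asarray(gap_prof, dtype=float)
    if prob.shape != gap_prof.shape:
        raise ValueError("probability and gap profile lengths differ")
    n = prob.size
    deriv = np.diff(prob) if n > 1 else np.zeros(0)
    gap_step = np.diff(gap_prof) if n > 1 else np.zeros(0)

    calls: list[RegionCall] = []
    for seed_start, seed_stop in _seed_runs(prob, high_cut):
        # left endpoint: outward = leftward, inward = rightward
        out_lo = seed_start
        while out_lo > 0 and prob[out_lo - 1] >= low_cut and abs(deriv[out_lo - 1]) >= d_out:
            out_lo -= 1
        in_hi = seed_start
        while in_hi < seed_stop - 1 and abs(deriv[in_hi]) >= d_in:
            in_hi += 1
        left = _boundary(out_lo - 1, in_hi - 1, deriv, gap_step) if n > 1 else seed_start
        left = min(max(left, 0), seed_start)
        # right endpoint: outward = rightward, inward = leftward
        out_hi = seed_stop
        while out_hi < n and prob[out_hi - 1] >= low_cut and abs(deriv[out_hi - 1]) >= d_out:
            out_hi += 1
        in_lo = seed_stop
        while in_lo > seed_start + 1 and abs(deriv[in_lo - 2]) >= d_in:
            in_lo -= 1
        right = _boundary(in_lo - 1, out_hi - 1, deriv, gap_step) if n > 1 else seed_stop
        right = min(max(right, seed_stop), n)
        calls.append(RegionCall(left, right, state, seed_start, seed_stop))

    merged: list[RegionCall] = []
    for call in sorted(calls, key=lambda c: (c.start, c.stop)):
        if merged and call.start <= merged[-1].stop:
            prev = merged[-1]
            merged[-1] = RegionCall(
                prev.start,
                max(prev.stop, call.stop),
                state,
                min(prev.seed_start, call.seed_start),
                max(prev.seed_stop, call.seed_stop),
            )
        else:
            merged.append(call)
    return merged


# ----------------------------------------------------------------------
# trimming
# ----------------------------------------------------------------------
def trim_state3(
    aln: BinaryAlignment,
    regions: Sequence[RegionCall],
    weights: SpeciesWeights,
    alpha: float = 0.01,
    mu_cap: float = 2.0,
    exclude_top: int = 5,
    min_count: int = 1,
) -> list[TrimAction]:
    """Per-sequence segment trims inside state-3 regions.

    The weighted mean non-gap count over sequences (excluding the
    ``exclude_top`` sequences with the most non-gap symbols) is capped at
    ``mu_cap`` to give the geometric parameter; every sequence whose
    non-gap count equals or exceeds the real-valued cutoff is trimmed.
    """
    actions: list[TrimAction] = []
    w = np.array([weights[s] for s in aln.species])
    for region in regions:
        if region.stop - region.start > aln.width:
            raise ValueError("region wider than alignment")
        counts = (~aln.is_gap[:, region.start : region.stop]).sum(axis=1)
        if counts.sum() == 0:
            continue
        order = np.argsort(-counts, kind="stable")
        included = order[exclude_top:] if exclude_top < len(order) else np.array([], dtype=int)
        if included.size and w[included].sum() > 0:
            mu = float((w[included] * counts[included]).sum() / w[included].sum())
        else:
            mu = float(counts.mean())
        mu = min(mu, mu_cap)
        k = geometric_cutoff(mu, alpha)
        for i in np.flatnonzero((counts >= k) & (counts >= min_count)):
            actions.append(TrimAction("segment", region.start, region.stop, aln.ids[int(i)]))
    return actions


def trim_state2(
    aln: BinaryAlignment,
    p2: np.ndarray,
    p3: np.ndarray,
    state3_regions: Sequence[RegionCall],
    gap_prof: np.ndarray,
    high_cut: float = STATE2_HIGH,
    low_cut: float = STATE3_LOW,
    d_out: float = STATE3_DERIV,
    d_in: float = STATE3_DERIV,
) -> tuple[list[RegionCall], list[TrimAction]]:
    """Column trims from the combined state-2 + masked state-3 posterior.

    The state-3 posterior is zeroed inside regions already trimmed at the
    segment level, so only genuinely intermediate regions contribute.
    """
    p3_masked = np.asarray(p3, dtype=float).copy()
    for region in state3_regions:
        p3_masked[region.start : region.stop] = 0.0
    combined = np.asarray(p2, dtype=float) + p3_masked
    regions = define_regions(combined, gap_prof, high_cut, low_cut, d_out, d_in, state=2)
    actions = [
        TrimAction("column", col, col + 1)
        for region in regions
        for col in range(region.start, region.stop)
    ]
    return regions, actions


def call_missing(
    seq_posterior: np.ndarray,
    seq_is_gap: np.ndarray,
    seed_cut: float = MISSING_SEED,
    stop_cut: float = MISSING_STOP,
    sequence_id: str = "",
) -> list[TrimAction]:
    """Missing-data segments for one sequence.

    Seeds are runs with posterior >= seed_cut; each seed expands outward
    until it reaches a non-gap symbol or the posterior drops below
    ``stop_cut``.  Overlapping or adjacent segments merge.
    """
    prob = np.asarray(seq_posterior, dtype=float)
    is_gap = np.asarray(seq_is_gap, dtype=bool)
    if prob.shape != is_gap.shape:
        raise ValueError("posterior and row lengths differ")
    segments: list[tuple[int, int]] = []
    for start, stop in _seed_runs(prob, seed_cut):
        lo = start
        while lo > 0 and is_gap[lo - 1] and prob[lo - 1] >= stop_cut:
            lo -= 1
        hi = stop
        while hi < prob.size and is_gap[hi] and prob[hi] >= stop_cut:
            hi += 1
        segments.append((lo, hi))
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(segments):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return [TrimAction("missing", lo, hi, sequence_id) for lo, hi in merged]


def format_segments(actions: Sequence[TrimAction]) -> str:
    """Serialize missing segments as 'start0-stop0,start1-stop1,...'."""
    return ",".join(f"{a.start}-{a.stop}" for a in actions)


# ----------------------------------------------------------------------
# application
# ----------------------------------------------------------------------
def apply_trims(
    ids: Sequence[str],
    rows: Sequence[str],
    actions: Sequence[TrimAction],
) -> list[str]:
    """Apply segment then column trims; missing actions are annotations only."""
    grid = [list(row) for row in rows]
    index = {seq_id: i for i, seq_id in enumerate(ids)}
    for action in actions:
        if action.kind != "segment":
            continue
        row = grid[index[action.sequence_id]]
        for j in range(action.start, action.stop):
            if row[j] not in "-.":
                row[j] = "-"
    drop = {a.start for a in actions if a.kind == "column"}
    keep = [j for j in range(len(grid[0]) if grid else 0) if j not in drop]
    return ["".join(row[j] for j in keep) for row in grid]
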