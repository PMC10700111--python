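"""Anchored two-stage realignment.

Highly conserved regions are located from a weighted non-gap mask; the
complementary diverged regions are extracted, realigned through an
adapter with a weaker over-alignment correction, and stitched back.
Conserved columns are never touched and every row's residue sequence is
invariant under the whole operation.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegionSpan",
    "close_mask",
    "conserved_regions",
    "refine",
]

DEFAULT_CLOSE_SIZE = 3
DEFAULT_MIN_LEN = 10
STRONG_A = 0.7
WEAK_A = 0.4


@dataclass(frozen=True)
class RegionSpan:
    start: int
    stop: int
    kind: str  # "conserved" | "diverged"

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise ValueError("empty span")
        if self.kind not in ("conserved", "diverged"):
            raise ValueError(f"bad span kind {self.kind!r}")


def close_mask(mask: np.ndarray, size: int = DEFAULT_CLOSE_SIZE) -> np.ndarray:
    """1-D morphological closing with a flat structuring element.

    Dilation treats positions outside the mask as False, erosion treats
    them as True, so runs touching the boundary are preserved.
    """
    if size % 2 != 1:
        raise ValueError("structuring element size must be odd")
    mask = np.asarray(mask, dtype=bool)
    half = size // 2
    padded = np.pad(mask, half, constant_values=False)
    dilated = np.zeros_like(mask)
    for off in range(size):
        dilated |= padded[off : off + mask.size]
    padded = np.pad(dilated, half, constant_values=True)
    eroded = np.ones_like(mask)
    for off in range(size):
        eroded &= padded[off : off + mask.size]
    return eroded


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, mask.size))
    return out


def conserved_regions(
    non_gap_fraction: np.ndarray,
    close_size: int = DEFAULT_CLOSE_SIZE,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[RegionSpan]:
    """Tile the alignment into conserved and diverged spans.

    Columns where the weighted non-gap fraction exceeds 0.5 form a boolean
    mask; the mask is closed once; runs of True with length >= min_len are
    conserved, everything else is diverged.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    frac = np.asarray(non_gap_fraction, dtype=float)
    mask = close_mask(frac > 0.5, close_size)
    conserved = [(s, e) for s, e in _runs(mask) if e - s >= min_len]
    spans: list[RegionSpan] = []
    cursor = 0
    for s, e in conserved:
        if cursor < s:
            spans.append(RegionSpan(cursor, s, "diverged"))
        spans.append(RegionSpan(s, e, "conserved"))
        cursor = e
    if cursor < frac.size:
        spans.append(RegionSpan(cursor, frac.size, "diverged"))
    return spans


def _degap(s: str) -> str:
    return s.replace("-", "").replace(".", "")


def refine(
    ids: Sequence[str],
    rows: Sequence[str],
    spans: Sequence[RegionSpan],
    adapter,
    weak_a: float = WEAK_A,
) -> list[str]:
    """Realign each diverged span through the adapter and stitch back.

    The adapter is called with the degapped residues of each row within
    the span; rows whose span content is entirely gaps re-enter as all-gap
    rows of the sub-alignment's width.  Conserved spans are copied
    verbatim.  Raises if the adapter returns a different sequence set or
    mutates residues.
    """
    pieces: list[list[str]] = [[] for _ in rows]
    for span in spans:
        segment = [row[span.start : span.stop] for row in rows]
        if span.kind == "conserved":
            for i, seg in enumerate(segment):
                pieces[i].append(seg)
            continue
        unaligned = {ids[i]: _degap(seg) for i, seg in enumerate(segment)}
        non_empty = {k: v for k, v in unaligned.items() if v}
        if not non_empty:
            continue  # all-gap span: replaced by zero columns
        sub = adapter.align(non_empty, weak_a)
        if set(sub) != set(non_empty):
            raise ValueError("adapter returned a different sequence set")
        widths = {len(v) for v in sub.values()}
        if len(widths) != 1:
            raise ValueError("adapter returned a ragged alignment")
        width = widths.pop()
        for name, aligned in sub.items():
            if _degap(aligned) != non_empty[name]:
                raise ValueError(f"adapter mutated residues of {name!r}")
        for i, seq_id in enumerate(ids):
            pieces[i].append(sub.get(seq_id, "-" * width))
    refined = ["".join(p) for p in pieces]
    for original, new in zip(rows, refined):
        if _degap(original) != _degap(new):
            raise AssertionError("refinement changed residue content")
    return refined
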