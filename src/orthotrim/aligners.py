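"""Aligner adapters used by the refinement stage.

An adapter receives unaligned sequences and an over-alignment correction
strength ``a_max`` in [0, 1] and must return an alignment containing
exactly those sequences with their residues in order.  The production
adapter shells out to MAFFT; the mock adapter is a deterministic
progressive Needleman-Wunsch used by the test suite so it never spawns a
subprocess.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .profile_weighting import read_fasta, write_fasta

__all__ = ["MafftAdapter", "MockProgressiveAligner", "IdentityAligner"]

MAFFT_ARGS = [
    "--globalpair",
    "--maxiterate",
    "1000",
    "--thread",
    "1",
    "--anysymbol",
    "--allowshift",
    "--leavegappyregion",
]


class MafftAdapter:
    """Adapter invoking ``mafft`` with over-alignment correction."""

    def __init__(self, executable: str = "mafft") -> None:
        self.executable = executable

    def available(self) -> bool:
        return shutil.which(self.executable) is not None

    def align(self, seqs: dict[str, str], a_max: float) -> dict[str, str]:
        if not seqs:
            return {}
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "in.fasta"
            write_fasta(inp, seqs)
            cmd = [self.executable, *MAFFT_ARGS, "--unalignlevel", str(a_max), str(inp)]
            proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
            out = Path(tmp) / "out.fasta"
            out.write_text(proc.stdout)
            aligned = read_fasta(out)
        return {name: aligned[name] for name in seqs}


class IdentityAligner:
    """Returns pre-aligned input unchanged (a fixed point for refinement)."""

    def __init__(self, alignment: dict[str, str]) -> None:
        self.alignment = alignment

    def align(self, seqs: dict[str, str], a_max: float) -> dict[str, str]:
        return {name: self.alignment[name] for name in seqs}


class MockProgressiveAligner:
    """Deterministic progressive aligner for tests.

    Sequences are added one at a time to a growing column profile with
    global Needleman-Wunsch.  ``a_max`` scales the mismatch penalty, so a
    strong correction refuses to align dissimilar residues and leaves
    them in their own columns.
    """

    def __init__(self, match: float = 2.0, gap: float = -1.0) -> None:
        self.match = match
        self.gap = gap

    def align(self, seqs: dict[str, str], a_max: float) -> dict[str, str]:
        names = list(seqs)
        if not names:
            return {}
        mismatch = -(1.0 + 4.0 * a_max)
        rows = [seqs[names[0]]]
        for name in names[1:]:
            rows = self._add(rows, seqs[name], mismatch)
        return dict(zip(names, rows))

    def _column_score(self, rows: list[str], j: int, c: str, mismatch: float) -> float:
        score = 0.0
        n = 0
        for row in rows:
            x = row[j]
            if x == "-":
                score += self.gap
            else:
                n += 1
                score += self.match if x == c else mismatch
        return score / max(len(rows), 1) if n else self.gap

    def _add(self, rows: list[str], seq: str, mismatch: float) -> list[str]:
        width = len(rows[0])
        n, m = width, len(seq)
        # dp[i][j]: best score aligning first i profile columns with first j chars
        neg = float("-inf")
        dp = [[neg] * (m + 1) for _ in range(n + 1)]
        move = [[0] * (m + 1) for _ in range(n + 1)]  # 1=diag 2=up(col vs gap) 3=left(char vs gap)
        dp[0][0] = 0.0
        for i in range(1, n + 1):
            dp[i][0] = dp[i - 1][0] + self.gap
            move[i][0] = 2
        for j in range(1, m + 1):
            dp[0][j] = dp[0][j - 1] + self.gap
            move[0][j] = 3
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                diag = dp[i - 1][j - 1] + self._column_score(rows, i - 1, seq[j - 1], mismatch)
                up = dp[i - 1][j] + self.gap
                left = dp[i][j - 1] + self.gap
                best = max(diag, up, left)
                dp[i][j] = best
                move[i][j] = 1 if best == diag else (2 if best == up else 3)
        # traceback
        out_cols: list[tuple[int | None, str | None]] = []
        i, j = n, m
        while i > 0 or j > 0:
            mv = move[i][j]
            if mv == 1:
                out_cols.append((i - 1, seq[j - 1]))
                i, j = i - 1, j - 1
            elif mv == 2:
                out_cols.append((i - 1, None))
                i -= 1
            else:
                out_cols.append((None, seq[j - 1]))
                j -= 1
        out_cols.reverse()
        new_rows = ["" for _ in rows]
        new_seq_row = []
        for col, char in out_cols:
            for r, row in enumerate(rows):
                new_rows[r] += row[col] if col is not None else "-"
            new_seq_row.append(char if char is not None else "-")
        return [*new_rows, "".join(new_seq_row)]
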