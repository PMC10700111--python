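"""Tree-derived sequence weights, binary profiles, and representative selection.

Alignments are coded into gap / non-gap symbols; species are weighted by
the minimum-variance (Altschul-Carroll-Lipman) combination implied by the
Brownian covariance of the species tree, and isoforms are scored against a
weighted binary profile of their orthologous group.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .trees import ArrayTree

__all__ = [
    "BinaryAlignment",
    "SpeciesWeights",
    "BinaryProfile",
    "gp_species_weights",
    "binary_profile",
    "score_sequence",
    "select_representatives",
    "gap_profile",
    "read_fasta",
    "write_fasta",
]

GAP_SYMBOLS = frozenset("-.")
DEFAULT_PSEUDOCOUNT = 0.005


def code_binary(sequence: str) -> np.ndarray:
    """True where the symbol is a gap ('-' or '.')."""
    return np.array([c in GAP_SYMBOLS for c in sequence], dtype=bool)


@dataclass
class BinaryAlignment:
    """A rectangular alignment coded into gap / non-gap cells.

    ``is_gap`` has shape (n_rows, n_columns).  ``species`` and ``genes``
    annotate rows; ``rows`` holds the original aligned strings when the
    alignment was built from sequences (may be None for synthetic data).
    """

    ids: list[str]
    species: list[str]
    genes: list[str]
    is_gap: np.ndarray
    rows: list[str] | None = None

    def __post_init__(self) -> None:
        self.is_gap = np.asarray(self.is_gap, dtype=bool)
        if self.is_gap.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        n = self.is_gap.shape[0]
        if not (len(self.ids) == len(self.species) == len(self.genes) == n):
            raise ValueError("row annotations do not match matrix shape")
        if self.rows is not None:
            if len(self.rows) != n or any(len(r) != self.width for r in self.rows):
                raise ValueError("alignment is not rectangular")

    @classmethod
    def from_rows(
        cls,
        ids: Sequence[str],
        rows: Sequence[str],
        species: Sequence[str],
        genes: Sequence[str],
    ) -> "BinaryAlignment":
        matrix = np.array([[c in GAP_SYMBOLS for c in row] for row in rows], dtype=bool)
        return cls(list(ids), list(species), list(genes), matrix, rows=list(rows))

    @property
    def n_rows(self) -> int:
        return self.is_gap.shape[0]

    @property
    def width(self) -> int:
        return self.is_gap.shape[1]

    def row_index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)


@dataclass
class SpeciesWeights:
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be positive")

    def __getitem__(self, species: str) -> float:
        return self.weights[species]


@dataclass
class BinaryProfile:
    """Per-column weighted counts for the non-gap and gap symbols."""

    non_gap: np.ndarray
    gap: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.non_gap.shape[0]


def gp_species_weights(tree: ArrayTree) -> SpeciesWeights:
    """Minimum-variance species weights from the tree's Brownian covariance.

    With cov(i, j) equal to the shared root-to-tip path length, the
    covariance is standardized to a correlation matrix and the weights
    solve ``R w = 1`` (normalized) — the minimum-variance unbiased
    combination of the standardized tip values.  Degenerate matrices
    (e.g. a zero-length star) fall back to the pseudo-inverse and, if
    that is still uninformative, to equal weights.
    """
    cov = tree.shared_path_covariance()
    n = cov.shape[0]
    # standardize to a correlation matrix so per-tip variance scale drops
    # out (two tips then weight equally regardless of branch lengths)
    d = np.sqrt(np.diag(cov))
    d[d == 0] = 1.0
    corr = cov / np.outer(d, d)
    ones = np.ones(n)
    try:
        raw = np.linalg.solve(corr, ones)
    except np.linalg.LinAlgError:
        raw = np.linalg.pinv(corr) @ ones
    if not np.all(np.isfinite(raw)) or raw.sum() <= 0:
        raw = ones
    raw = np.maximum(raw, 1e-12)
    raw = raw / raw.sum()
    return SpeciesWeights(dict(zip(tree.tip_labels, raw)))


def _gene_weights(aln: BinaryAlignment, weights: SpeciesWeights) -> dict[str, float]:
    """Per-gene weight: the species weight split evenly over its genes."""
    genes_per_species: dict[str, set[str]] = {}
    for species, gene in zip(aln.species, aln.genes):
        if species not in weights.weights:
            raise KeyError(f"row species {species!r} has no weight")
        genes_per_species.setdefault(species, set()).add(gene)
    out: dict[str, float] = {}
    for species, gene in zip(aln.species, aln.genes):
        out[gene] = weights[species] / len(genes_per_species[species])
    return out


def binary_profile(
    aln: BinaryAlignment,
    weights: SpeciesWeights,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BinaryProfile:
    """Weighted per-column gap / non-gap counts.

    Rows are grouped by gene; a group contributes its weight to the
    non-gap count at a column when at least one of its rows is aligned
    there, and to the gap count otherwise.  Species with several genes in
    the alignment split their weight evenly among them.
    """
    gene_w = _gene_weights(aln, weights)
    non_gap = np.full(aln.width, pseudocount, dtype=float)
    gap = np.full(aln.width, pseudocount, dtype=float)
    seen: set[str] = set()
    for gene in aln.genes:
        if gene in seen:
            continue
        seen.add(gene)
        rows = [i for i, g in enumerate(aln.genes) if g == gene]
        any_aligned = ~np.all(aln.is_gap[rows], axis=0)
        non_gap += np.where(any_aligned, gene_w[gene], 0.0)
        gap += np.where(any_aligned, 0.0, gene_w[gene])
    return BinaryProfile(non_gap=non_gap, gap=gap, pseudocount=pseudocount)


def score_sequence(profile: BinaryProfile, coded_row: np.ndarray) -> float:
    """Log-likelihood of a coded row under the profile (natural log)."""
    coded_row = np.asarray(coded_row, dtype=bool)
    if coded_row.shape[0] != profile.width:
        raise ValueError("row length does not match profile width")
    total = profile.non_gap + profile.gap
    counts = np.where(coded_row, profile.gap, profile.non_gap)
    return float(np.sum(np.log(counts / total)))


def select_representatives(aln: BinaryAlignment, profile: BinaryProfile) -> dict[str, str]:
    """Per gene, the accession of the row maximizing the profile score.

    Ties are broken by accession sort order.
    """
    best: dict[str, tuple[float, str]] = {}
    for i, (seq_id, gene) in enumerate(zip(aln.ids, aln.genes)):
        score = score_sequence(profile, aln.is_gap[i])
        cur = best.get(gene)
        if cur is None or (-score, seq_id) < (-cur[0], cur[1]):
            best[gene] = (score, seq_id)
    return {gene: seq_id for gene, (_, seq_id) in best.items()}


def gap_profile(aln: BinaryAlignment, weights: SpeciesWeights) -> np.ndarray:
    """Per-column weighted gap fraction (single-copy context: one row per species)."""
    w = np.array([weights[s] for s in aln.species])
    return (w[:, None] * aln.is_gap).sum(axis=0)


# ----------------------------------------------------------------------
# FASTA I/O (aligned or unaligned)
# ----------------------------------------------------------------------
def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records[name] = "".join(chunks)
    return records


def write_fasta(path, records: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
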