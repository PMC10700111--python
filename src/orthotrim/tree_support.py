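"""Meta-alignment sampling, reverse translation, and consensus trees."""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "SamplingStrategy",
    "sample_meta_alignment",
    "ReverseTranslation",
    "reverse_translate",
    "ConsensusTree",
    "consensus_tree",
    "tree_bipartitions",
]

GAP_CHARS = frozenset("-.")


# ----------------------------------------------------------------------
# meta-alignment sampling
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SamplingStrategy:
    n_columns: int
    allow_invariant: bool = True
    max_gap_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_columns <= 0:
            raise ValueError("n_columns must be positive")
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must lie in [0, 1]")


def _column_eligible(column: Sequence[str], strategy: SamplingStrategy) -> bool:
    gaps = sum(1 for c in column if c in GAP_CHARS)
    if gaps > strategy.max_gap_fraction * len(column):
        return False
    if not strategy.allow_invariant:
        residues = {c for c in column if c not in GAP_CHARS}
        if len(residues) <= 1:
            return False
    return True


def sample_meta_alignment(
    alignments: Sequence[Mapping[str, str]],
    strategy: SamplingStrategy,
) -> dict[str, str]:
    """Draw columns uniformly with replacement from the pooled eligible set.

    All alignments must be keyed by the same species set; the output is a
    species -> string alignment of width ``strategy.n_columns``.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    species = sorted(alignments[0])
    pool: list[tuple[str, ...]] = []
    for aln in alignments:
        if sorted(aln) != species:
            raise ValueError("alignments span different species sets")
        width = len(next(iter(aln.values())))
        for j in range(width):
            column = tuple(aln[s][j] for s in species)
            if _column_eligible(column, strategy):
                pool.append(column)
    if not pool:
        raise ValueError("no eligible columns under the sampling strategy")
    rng = np.random.default_rng(strategy.seed)
    chosen = rng.integers(0, len(pool), size=strategy.n_columns)
    rows = {s: [] for s in species}
    for idx in chosen:
        for s, c in zip(species, pool[idx]):
            rows[s].append(c)
    return {s: "".join(chars) for s, chars in rows.items()}


# ----------------------------------------------------------------------
# reverse translation
# ----------------------------------------------------------------------
@dataclass
class ReverseTranslation:
    accepted: bool
    rows: dict[str, str] = field(default_factory=dict)
    reason: str | None = None


def reverse_translate(
    protein_aln: Mapping[str, str],
    cds_map: Mapping[str, str],
    codon_table: int = 1,
) -> ReverseTranslation:
    """Expand each protein alignment row into codons from its CDS.

    Each residue becomes its codon and each gap becomes three gaps.  The
    whole alignment is rejected (flagged, not raised) when any CDS fails
    to translate to its degapped protein row, has a length not divisible
    by 3, or is missing.  A single trailing stop codon is tolerated.
    """
    table = CodonTable.unambiguous_dna_by_id[codon_table]
    rows: dict[str, str] = {}
    for name, aligned in protein_aln.items():
        cds = cds_map.get(name)
        if cds is None:
            return ReverseTranslation(False, reason=f"{name}: no coding sequence")
        if len(cds) % 3 != 0:
            return ReverseTranslation(False, reason=f"{name}: CDS length not divisible by 3")
        translated = str(Seq(cds).translate(table=codon_table))
        if translated.endswith("*"):
            translated = translated[:-1]
            cds = cds[:-3]
        protein = "".join(c for c in aligned if c not in GAP_CHARS)
        if translated != protein:
            return ReverseTranslation(False, reason=f"{name}: translation mismatch")
        codons = [cds[3 * i : 3 * i + 3] for i in range(len(protein))]
        out, k = [], 0
        for c in aligned:
            if c in GAP_CHARS:
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        rows[name] = "".join(out)
    return ReverseTranslation(True, rows=rows)


# ----------------------------------------------------------------------
# consensus trees
# ----------------------------------------------------------------------
def _normalize_split(leaves: frozenset[str], taxa: frozenset[str], ref: str) -> frozenset[str]:
    return leaves if ref not in leaves else taxa - leaves


def tree_bipartitions(newick: str) -> tuple[frozenset[str], set[frozenset[str]]]:
    """Non-trivial bipartitions of a newick tree, as leaf sets not
    containing the lexicographically smallest taxon."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        split = _normalize_split(frozenset(clade), taxa, ref)
        if 2 <= len(split) <= len(taxa) - 2:
            splits.add(split)
    return taxa, splits


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    # normalized splits (reference taxon outside both): laminar test
    return a.isdisjoint(b) or a <= b or b <= a


@dataclass
class ConsensusTree:
    taxa: frozenset[str]
    splits: dict[frozenset[str], float]  # split -> support percentage

    def to_newick(self) -> str:
        ref = min(self.taxa)
        ordered = sorted(self.splits, key=len)
        children: dict[frozenset[str], list] = {s: [] for s in ordered}
        top: list = []
        placed: set[frozenset[str]] = set()
        for s in ordered:
            parent = None
            for t in sorted(self.splits, key=len):
                if len(t) > len(s) and s < t:
                    if parent is None or len(t) < len(parent):
                        parent = t
            (children[parent] if parent is not None else top).append(s)
            placed.add(s)
        leaf_parent: dict[str, frozenset[str] | None] = {}
        for taxon in self.taxa - {ref}:
            parent = None
            for t in ordered:
                if taxon in t and (parent is None or len(t) < len(parent)):
                    parent = t
            leaf_parent[taxon] = parent

        def render(split: frozenset[str]) -> str:
            parts = [render(c) for c in sorted(children[split], key=lambda x: sorted(x))]
            parts += sorted(t for t, p in leaf_parent.items() if p == split)
            support = self.splits[split]
            return f"({','.join(parts)}){support:g}"

        parts = [render(c) for c in sorted(top, key=lambda x: sorted(x))]
        parts += sorted(t for t, p in leaf_parent.items() if p is None)
        return f"({ref},{','.join(parts)});"


def consensus_tree(newicks: Sequence[str], mode: str = "majority") -> ConsensusTree:
    """Majority (>50%) or loose (greedy compatible) consensus of trees.

    Loose mode adds compatible bipartitions in descending frequency, ties
    broken by the lexicographically smallest split, until no more can be
    added; it always contains every majority bipartition.
    """
    if mode not in ("majority", "loose"):
        raise ValueError(f"unknown mode {mode!r}")
    if not newicks:
        raise ValueError("no trees supplied")
    counts: dict[frozenset[str], int] = {}
    taxa0: frozenset[str] | None = None
    for newick in newicks:
        taxa, splits = tree_bipartitions(newick)
        if taxa0 is None:
            taxa0 = taxa
        elif taxa != taxa0:
            raise ValueError("trees span different tip sets")
        for s in splits:
            counts[s] = counts.get(s, 0) + 1
    n = len(newicks)
    if mode == "majority":
        chosen = {s: 100.0 * c / n for s, c in counts.items() if c > n / 2}
        return ConsensusTree(taxa0, chosen)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))
    accepted: dict[frozenset[str], float] = {}
    for split, count in ordered:
        if all(_compatible(split, other) for other in accepted):
            accepted[split] = 100.0 * count / n
    return ConsensusTree(taxa0, accepted)
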