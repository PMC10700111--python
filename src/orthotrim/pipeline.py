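"""Stage orchestration: raw HSPs -> edges -> groups, and alignment curation.

These drivers glue the per-module operations together in the order the
pipeline runs them; they are shared by the CLI and the end-to-end tests.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from . import hit_processing as hp
from .alignment_curation import (
    STATE2_HIGH,
    STATE3_DERIV,
    STATE3_HIGH,
    STATE3_LOW,
    STATE3_MASK_CUT,
    RegionCall,
    TrimAction,
    call_missing,
    define_regions,
    trim_state2,
    trim_state3,
)
from .phylo_hmm import HMMSpec, MissingEmission, forward_backward
from .profile_weighting import BinaryAlignment, SpeciesWeights, gap_profile

__all__ = [
    "derive_edges",
    "best_self_hits",
    "inter_genome_max_scores",
    "CurationResult",
    "curate_alignment",
    "decode_missing",
]


def _group_by(hsps: Sequence[hp.HSP], key) -> dict:
    out: dict = {}
    for h in hsps:
        out.setdefault(key(h), []).append(h)
    return out


def best_inter_genome_hits(
    hsps: Sequence[hp.HSP],
    query_lengths: Mapping[str, int],
    species_of: Mapping[str, str],
) -> list[hp.Hit]:
    """Per (query, target genome): best-gene extraction, merging, best hit."""
    best: list[hp.Hit] = []
    per_direction = _group_by(hsps, lambda h: (h.query_accession, species_of[h.target_accession]))
    for (query, _target_sp), group in sorted(per_direction.items()):
        candidates = hp.extract_best_gene_hsps(group)
        hits = []
        for _target, pair_hsps in sorted(
            _group_by(candidates, lambda h: h.target_accession).items()
        ):
            hit = hp.merge_hsps(pair_hsps, query_lengths[query])
            if hit is not None:
                hits.append(hit)
        chosen = hp.select_best_hit(hits)
        if chosen is not None:
            best.append(chosen)
    return best


def derive_edges(
    hsps: Sequence[hp.HSP],
    query_lengths: Mapping[str, int],
    species_of: Mapping[str, str],
) -> dict[tuple[str, str], float]:
    """Reciprocal best-hit edges from inter-genome HSPs."""
    best = best_inter_genome_hits(hsps, query_lengths, species_of)
    return hp.apply_hit_filters(best)


def best_self_hits(
    self_hsps: Sequence[hp.HSP],
    query_lengths: Mapping[str, int],
) -> list[hp.Hit]:
    """Per (query, target gene) best hits from self-search output.

    The best-gene extraction step is skipped; grouping by target gene
    keeps only the highest-scoring isoform per gene.
    """
    best: list[hp.Hit] = []
    per_pair = _group_by(self_hsps, lambda h: (h.query_accession, h.target_gene))
    for (query, _gene), group in sorted(per_pair.items()):
        hits = []
        for _target, pair_hsps in sorted(
            _group_by(group, lambda h: h.target_accession).items()
        ):
            hit = hp.merge_hsps(pair_hsps, query_lengths[query])
            if hit is not None:
                hits.append(hit)
        chosen = hp.select_best_hit(hits)
        if chosen is not None:
            best.append(chosen)
    return best


def inter_genome_max_scores(best_hits: Sequence[hp.Hit]) -> dict[str, float]:
    out: dict[str, float] = {}
    for hit in best_hits:
        cur = out.get(hit.query_accession)
        if cur is None or hit.disjoint_score > cur:
            out[hit.query_accession] = hit.disjoint_score
    return out


# ----------------------------------------------------------------------
# curation driver
# ----------------------------------------------------------------------
@dataclass
class CurationResult:
    state3_regions: list[RegionCall]
    state2_regions: list[RegionCall]
    actions: list[TrimAction] = field(default_factory=list)
    posteriors: np.ndarray | None = None


def _columns_by_tree(aln: BinaryAlignment, tip_labels: Sequence[str]) -> np.ndarray:
    row_of = {s: i for i, s in enumerate(aln.species)}
    missing = [s for s in tip_labels if s not in row_of]
    if missing:
        raise KeyError(f"alignment lacks rows for species {missing}")
    order = [row_of[s] for s in tip_labels]
    return (~aln.is_gap[order]).astype(int)


def curate_alignment(
    aln: BinaryAlignment,
    weights: SpeciesWeights,
    insertion_spec: HMMSpec,
    state2_index: int,
    state3_index: int,
    alpha: float = 0.01,
) -> CurationResult:
    """Insertion-model posterior decoding plus both trimming passes.

    The state-3 posterior is zeroed where the weighted gap profile is at
    most 0.1 before region definition, segment trims are derived with the
    geometric cutoff, and the residual state-2 + masked state-3 posterior
    drives column trims.
    """
    tree = insertion_spec.emission.tree
    columns = _columns_by_tree(aln, tree.tip_labels)
    posteriors = forward_backward(insertion_spec, columns).posteriors
    gp = gap_profile(aln, weights)

    p3 = posteriors[:, state3_index].copy()
    p3[gp <= STATE3_MASK_CUT] = 0.0
    regions3 = define_regions(p3, gp, STATE3_HIGH, STATE3_LOW, STATE3_DERIV, STATE3_DERIV)
    actions = trim_state3(aln, regions3, weights, alpha=alpha)

    p2 = posteriors[:, state2_index]
    regions2, column_actions = trim_state2(
        aln, p2, p3, regions3, gp, high_cut=STATE2_HIGH
    )
    actions.extend(column_actions)
    return CurationResult(
        state3_regions=regions3,
        state2_regions=regions2,
        actions=actions,
        posteriors=posteriors,
    )


def decode_missing(
    aln: BinaryAlignment,
    missing_spec_factory,
    missing_state_index: int = 1,
) -> dict[str, list[TrimAction]]:
    """Per-sequence missing-segment calls.

    ``missing_spec_factory(focal_species)`` must return an
    :class:`HMMSpec` whose emission is a :class:`MissingEmission` for that
    focal tip.
    """
    out: dict[str, list[TrimAction]] = {}
    for i, (seq_id, species) in enumerate(zip(aln.ids, aln.species)):
        spec = missing_spec_factory(species)
        emission: MissingEmission = spec.emission
        columns = _columns_by_tree(aln, emission.tree.tip_labels)
        posterior = forward_backward(spec, columns).posteriors[:, missing_state_index]
        out[seq_id] = call_missing(posterior, aln.is_gap[i], sequence_id=seq_id)
    return out
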