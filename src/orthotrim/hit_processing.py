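"""Homology-search postprocessing: HSP extraction, merging, and filtering.

The functions here transform raw tabular search output into an undirected
reciprocal-best-hit edge list plus a set of within-genome paralog pairs.
Intervals are 0-based half-open throughout; the 1-based closed coordinates
of BLAST tabular output are converted at parse time.
"""

from __future__ import annotations

import csv
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

__all__ = [
    "ProteinRecord",
    "HSP",
    "Hit",
    "ParalogPair",
    "deduplicate_proteins",
    "filter_by_evalue",
    "extract_best_gene_hsps",
    "merge_hsps",
    "select_best_hit",
    "apply_hit_filters",
    "detect_paralogs",
    "parse_blast_tab",
    "read_gene_map",
    "write_edges",
    "write_paralog_pairs",
]

DEFAULT_EVALUE_CUTOFF = 1e-10
MIN_QUERY_COVERAGE = 0.5


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein sequence."""

    accession: str
    gene_id: str
    species_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.accession}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.accession}: length does not match sequence")


@dataclass
class HSP:
    """One local alignment between a query and target sequence."""

    query_accession: str
    target_accession: str
    query_gene: str
    target_gene: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    bit_score: float
    e_value: float
    disjoint: bool = False
    compatible: bool = False

    def __post_init__(self) -> None:
        for start, stop in (self.query_interval, self.target_interval):
            if start >= stop:
                raise ValueError("interval start must be < stop")
        if self.bit_score < 0 or self.e_value < 0:
            raise ValueError("bit score and E-value must be non-negative")


@dataclass
class Hit:
    """Merged representation of all HSPs for one query-target pair."""

    query_accession: str
    target_accession: str
    hsps: list[HSP]
    disjoint_score: float
    query_coverage: float


@dataclass(frozen=True)
class ParalogPair:
    """An unordered within-species pair of likely paralogous sequences."""

    accession_a: str
    accession_b: str
    bit_score: float

    def __post_init__(self) -> None:
        if self.accession_a > self.accession_b:
            a, b = self.accession_b, self.accession_a
            object.__setattr__(self, "accession_a", a)
            object.__setattr__(self, "accession_b", b)

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.accession_a, self.accession_b)))


# ----------------------------------------------------------------------
# de-duplication and simple filters
# ----------------------------------------------------------------------
def deduplicate_proteins(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Keep the first accession for each (sequence, gene) pair per species.

    Distinct isoform sequences of a gene are all retained; identical
    sequences under different genes are retained as well (the rule is per
    gene, not global).
    """
    seen_accessions: dict[str, set[str]] = {}
    seen_pairs: set[tuple[str, str, str]] = set()
    out: list[ProteinRecord] = []
    for rec in records:
        accs = seen_accessions.setdefault(rec.species_id, set())
        if rec.accession in accs:
            raise ValueError(
                f"duplicate accession {rec.accession!r} in species {rec.species_id!r}"
            )
        accs.add(rec.accession)
        if rec.sequence is None:
            raise ValueError(f"{rec.accession}: sequence required for de-duplication")
        key = (rec.species_id, rec.gene_id, rec.sequence)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        out.append(rec)
    return out


def filter_by_evalue(hsps: Iterable[HSP], cutoff: float = DEFAULT_EVALUE_CUTOFF) -> list[HSP]:
    """Retain HSPs with E-value <= cutoff (inclusive boundary)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return [h for h in hsps if h.e_value <= cutoff]


# ----------------------------------------------------------------------
# best-gene extraction
# ----------------------------------------------------------------------
def extract_best_gene_hsps(hsps_for_query: Sequence[HSP]) -> list[HSP]:
    """Collect HSPs of target proteins belonging to the best-scoring gene(s).

    HSPs are grouped by target protein and groups are ranked by their
    maximum bit score.  Groups are emitted in rank order until a group's
    parent gene is not among the genes tied for the top-ranked score.
    """
    if not hsps_for_query:
        return []
    groups: dict[str, list[HSP]] = {}
    for h in hsps_for_query:
        groups.setdefault(h.target_accession, []).append(h)
    ranked = sorted(
        groups.items(),
        key=lambda kv: (-max(h.bit_score for h in kv[1]), kv[0]),
    )
    top_score = max(h.bit_score for h in ranked[0][1])
    top_genes = {
        hs[0].target_gene
        for _, hs in ranked
        if max(h.bit_score for h in hs) == top_score
    }
    out: list[HSP] = []
    for _, group in ranked:
        if group[0].target_gene not in top_genes:
            break
        out.extend(group)
    return out


# ----------------------------------------------------------------------
# HSP merging
# ----------------------------------------------------------------------
def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total, cur_start, cur_stop = 0, None, None
    for start, stop in ivs:
        if cur_stop is None or start > cur_stop:
            if cur_stop is not None:
                total += cur_stop - cur_start
            cur_start, cur_stop = start, stop
        else:
            cur_stop = max(cur_stop, stop)
    if cur_stop is not None:
        total += cur_stop - cur_start
    return total


def merge_hsps(hsps_for_pair: Sequence[HSP], query_length: int) -> Hit | None:
    """Merge the HSPs of one query-target pair into a single hit.

    Pass 1 (descending bit score) marks an HSP disjoint when its query
    interval does not overlap any previously marked disjoint HSP.  Pass 2
    seeds the compatible set with the disjoint set and then admits HSPs
    whose overlap with every compatible HSP is at most 50% of the length
    of either interval.  The greedy pass-1 choice deliberately favors few
    long HSPs over many short ones and may be score-suboptimal.
    """
    if not hsps_for_pair:
        return None
    order = sorted(
        hsps_for_pair,
        key=lambda h: (-h.bit_score, h.query_interval, h.target_interval),
    )
    marked = [replace(h, disjoint=False, compatible=False) for h in order]
    disjoint: list[HSP] = []
    for h in marked:
        if all(_overlap(h.query_interval, d.query_interval) == 0 for d in disjoint):
            h.disjoint = True
            h.compatible = True
            disjoint.append(h)
    compatible = list(disjoint)
    for h in marked:
        if h.disjoint:
            continue
        ok = True
        for c in compatible:
            ov = _overlap(h.query_interval, c.query_interval)
            la = h.query_interval[1] - h.query_interval[0]
            lb = c.query_interval[1] - c.query_interval[0]
            if ov > 0.5 * la or ov > 0.5 * lb:
                ok = False
                break
        if ok:
            h.compatible = True
            compatible.append(h)
    covered = _interval_union_length(c.query_interval for c in compatible)
    return Hit(
        query_accession=marked[0].query_accession,
        target_accession=marked[0].target_accession,
        hsps=marked,
        disjoint_score=sum(h.bit_score for h in disjoint),
        query_coverage=covered / query_length,
    )


def select_best_hit(hits_for_query: Sequence[Hit]) -> Hit | None:
    """Arg-max over disjoint score; ties broken by target accession."""
    if not hits_for_query:
        return None
    return min(hits_for_query, key=lambda h: (-h.disjoint_score, h.target_accession))


# ----------------------------------------------------------------------
# edge derivation
# ----------------------------------------------------------------------
def apply_hit_filters(
    best_hits: Iterable[Hit],
    min_coverage: float = MIN_QUERY_COVERAGE,
) -> dict[tuple[str, str], float]:
    """Apply overlap then reciprocity filters to directed best hits.

    Returns an undirected edge map keyed by the sorted accession pair;
    the edge score is the max of the two directed disjoint scores.
    """
    surviving: dict[tuple[str, str], float] = {}
    for hit in best_hits:
        if hit.query_coverage >= min_coverage:
            surviving[(hit.query_accession, hit.target_accession)] = hit.disjoint_score
    edges: dict[tuple[str, str], float] = {}
    for (q, t), score in surviving.items():
        if q == t:
            continue
        rev = surviving.get((t, q))
        if rev is None:
            continue
        key = (q, t) if q < t else (t, q)
        edges[key] = max(score, rev)
    return edges


def detect_paralogs(
    self_hits: Iterable[Hit],
    inter_genome_best_scores: Mapping[str, float],
    min_coverage: float = MIN_QUERY_COVERAGE,
) -> list[ParalogPair]:
    """Emit within-genome pairs scoring above all inter-genome best hits.

    ``self_hits`` are merged per (query, target gene), keeping the
    highest-scoring isoform; the best-gene extraction step is *not*
    applied to self-search output.  A pair is emitted when the forward
    hit's disjoint score strictly exceeds the query's maximum inter-genome
    best-hit score (absent queries compare against -inf), the forward hit
    passes the coverage filter, and a reciprocal hit passing coverage
    exists.
    """
    covered: dict[tuple[str, str], Hit] = {}
    for hit in self_hits:
        if hit.query_accession == hit.target_accession:
            continue
        if hit.query_coverage >= min_coverage:
            covered[(hit.query_accession, hit.target_accession)] = hit
    pairs: dict[tuple[str, str], ParalogPair] = {}
    for (q, t), hit in covered.items():
        if (t, q) not in covered:
            continue
        ceiling = inter_genome_best_scores.get(q, -math.inf)
        if hit.disjoint_score > ceiling:
            key = tuple(sorted((q, t)))
            score = max(hit.disjoint_score, covered[(t, q)].disjoint_score)
            prev = pairs.get(key)
            if prev is None or score > prev.bit_score:
                pairs[key] = ParalogPair(key[0], key[1], score)
    return [pairs[k] for k in sorted(pairs)]


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def read_gene_map(path) -> dict[str, tuple[str, str]]:
    """Read a TSV of (species_id, gene_id, accession) into accession -> (species, gene)."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            species_id, gene_id, accession = row[:3]
            out[accession] = (species_id, gene_id)
    return out


def parse_blast_tab(
    path,
    gene_map: Mapping[str, tuple[str, str]],
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> tuple[list[HSP], dict[str, int]]:
    """Parse BLAST tabular output into HSPs and query lengths.

    Expected column layout (``-outfmt "6 qseqid sseqid bitscore evalue
    qstart qend sstart send qlen slen"``).  Comment lines (outfmt 7) are
    skipped; 1-based closed coordinates become 0-based half-open.
    """
    hsps: list[HSP] = []
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            qseqid, sseqid = fields[0], fields[1]
            bitscore, evalue = float(fields[2]), float(fields[3])
            qstart, qend, sstart, send = (int(x) for x in fields[4:8])
            qlen = int(fields[8])
            if evalue > evalue_cutoff:
                continue
            if qseqid not in gene_map:
                raise KeyError(f"accession {qseqid!r} missing from gene map")
            if sseqid not in gene_map:
                raise KeyError(f"accession {sseqid!r} missing from gene map")
            hsps.append(
                HSP(
                    query_accession=qseqid,
                    target_accession=sseqid,
                    query_gene=gene_map[qseqid][1],
                    target_gene=gene_map[sseqid][1],
                    query_interval=(qstart - 1, qend),
                    target_interval=(sstart - 1, send),
                    bit_score=bitscore,
                    e_value=evalue,
                )
            )
            lengths[qseqid] = qlen
    return hsps, lengths


def write_edges(path, edges: Mapping[tuple[str, str], float]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for (a, b), score in sorted(edges.items()):
            writer.writerow([a, b, f"{score:g}"])


def write_paralog_pairs(path, pairs: Iterable[ParalogPair]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in sorted(pairs, key=lambda p: p.key):
            writer.writerow([p.accession_a, p.accession_b, f"{p.bit_score:g}"])
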