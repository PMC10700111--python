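"""Hit-graph clustering: k-clique percolation, paralog augmentation,
gene-level grouping, and single-copy selection."""

from __future__ import annotations

import csv
import time
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import networkx as nx

__all__ = [
    "PercolationTimeout",
    "OrthoGroup",
    "GeneGroup",
    "DiversityCriteria",
    "build_hit_graph",
    "clique_percolation",
    "k_core_fallback",
    "cluster_graph",
    "add_paralogs",
    "group_by_gene",
    "select_single_copy",
    "write_groups",
    "write_gene_groups",
]

DEFAULT_K = 4
DEFAULT_TIMEOUT = 90.0


class PercolationTimeout(Exception):
    """Raised when a percolation phase exceeds its time or work budget."""


@dataclass
class OrthoGroup:
    group_id: str
    members: frozenset[str]
    parent_genes: frozenset[tuple[str, str]] = frozenset()
    species: frozenset[str] = frozenset()

    @classmethod
    def from_members(cls, group_id: str, members: Iterable[str], graph: nx.Graph) -> "OrthoGroup":
        members = frozenset(members)
        if not members:
            raise ValueError("empty orthogroup")
        genes = frozenset(
            (graph.nodes[m]["species"], graph.nodes[m]["gene"]) for m in members
        )
        return cls(
            group_id=group_id,
            members=members,
            parent_genes=genes,
            species=frozenset(s for s, _ in genes),
        )


@dataclass
class GeneGroup:
    group_id: str
    orthogroup_ids: frozenset[str]
    union_genes: frozenset[tuple[str, str]]


@dataclass
class DiversityCriteria:
    """Named species sets with per-set minimum-presence counts."""

    sets: dict[str, frozenset[str]]
    minima: dict[str, int]

    def __post_init__(self) -> None:
        for name, minimum in self.minima.items():
            if name not in self.sets:
                raise ValueError(f"minimum given for unknown set {name!r}")
            if minimum > len(self.sets[name]):
                raise ValueError(f"minimum for {name!r} exceeds set size")

    def validate_species(self, known: Iterable[str]) -> None:
        known = set(known)
        for name, members in self.sets.items():
            unknown = members - known
            if unknown:
                raise ValueError(f"criteria set {name!r} references unknown species {sorted(unknown)}")

    def passes(self, species: frozenset[str]) -> bool:
        return all(
            len(species & self.sets[name]) >= minimum
            for name, minimum in self.minima.items()
        )


# ----------------------------------------------------------------------
# graph construction
# ----------------------------------------------------------------------
def build_hit_graph(
    edges: Mapping[tuple[str, str], float],
    node_attrs: Mapping[str, tuple[str, str]],
) -> nx.Graph:
    """Build a simple undirected graph from an edge map.

    ``node_attrs`` maps accession -> (species_id, gene_id).
    """
    graph = nx.Graph()
    for (a, b), score in edges.items():
        if a == b:
            continue
        graph.add_edge(a, b, score=score)
    for node in graph.nodes:
        if node not in node_attrs:
            raise KeyError(f"no (species, gene) attributes for node {node!r}")
        species, gene = node_attrs[node]
        graph.nodes[node]["species"] = species
        graph.nodes[node]["gene"] = gene
    return graph


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
class _Budget:
    """Wall-clock timeout with an optional deterministic work-unit cap."""

    def __init__(self, timeout: float | None, max_work: int | None) -> None:
        self.deadline = None if timeout is None else time.monotonic() + timeout
        self.max_work = max_work
        self.work = 0

    def tick(self, units: int = 1) -> None:
        self.work += units
        if self.max_work is not None and self.work > self.max_work:
            raise PercolationTimeout("work budget exceeded")
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise PercolationTimeout("wall-clock timeout exceeded")


def clique_percolation(
    component: nx.Graph,
    k: int = DEFAULT_K,
    timeout: float | None = DEFAULT_TIMEOUT,
    max_work: int | None = None,
) -> list[frozenset[str]]:
    """Cluster one connected component by k-clique percolation.

    Maximal cliques of size >= k are enumerated, then attached
    progressively to known communities: a clique joins every community
    with which it shares >= k-1 nodes through any member clique, merging
    communities bridged by the same clique.  Two maximal cliques of size
    >= k share >= k-1 nodes iff some k-clique of one is adjacent to some
    k-clique of the other, so communities equal the components of the
    k-clique adjacency graph.  Clusters may overlap in nodes.

    Raises :class:`PercolationTimeout` when either phase exceeds its
    budget; callers should fall back to :func:`k_core_fallback`.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    budget = _Budget(timeout, max_work)
    cliques: list[frozenset[str]] = []
    for clique in nx.find_cliques(component):
        budget.tick()
        if len(clique) >= k:
            cliques.append(frozenset(clique))
    # Each community is a list of member cliques plus its node union.
    communities: list[list[frozenset[str]]] = []
    for clique in cliques:
        attached: list[int] = []
        for ci, members in enumerate(communities):
            for other in members:
                budget.tick()
                if len(clique & other) >= k - 1:
                    attached.append(ci)
                    break
        if not attached:
            communities.append([clique])
        else:
            keep = communities[attached[0]]
            keep.append(clique)
            for ci in reversed(attached[1:]):
                keep.extend(communities.pop(ci))
    clusters = [frozenset().union(*members) for members in communities]
    return sorted(clusters, key=lambda c: sorted(c))


def k_core_fallback(component: nx.Graph, k: int = DEFAULT_K) -> list[frozenset[str]]:
    """Connected components of the subgraph with all degrees >= k-1.

    A k-clique's nodes have internal degree k-1, which makes the fallback
    threshold consistent with the percolation clique size.
    """
    core = nx.k_core(component, k - 1)
    clusters = [frozenset(c) for c in nx.connected_components(core)]
    return sorted(clusters, key=lambda c: sorted(c))


def cluster_graph(
    graph: nx.Graph,
    k: int = DEFAULT_K,
    timeout: float | None = DEFAULT_TIMEOUT,
    max_work: int | None = None,
) -> list[OrthoGroup]:
    """Cluster every connected component, falling back to the k-core on timeout."""
    groups: list[OrthoGroup] = []
    counter = 0
    for comp_nodes in sorted(nx.connected_components(graph), key=lambda c: sorted(c)):
        component = graph.subgraph(comp_nodes)
        try:
            clusters = clique_percolation(component, k, timeout=timeout, max_work=max_work)
        except PercolationTimeout:
            clusters = k_core_fallback(component, k)
        for cluster in clusters:
            groups.append(OrthoGroup.from_members(f"OG{counter:05d}", cluster, graph))
            counter += 1
    return groups


# ----------------------------------------------------------------------
# postprocessing
# ----------------------------------------------------------------------
def add_paralogs(
    groups: Sequence[OrthoGroup],
    pairs: Iterable,
    node_attrs: Mapping[str, tuple[str, str]],
) -> list[OrthoGroup]:
    """Add, for each original member, its paralog partners (one step only).

    Partners of added members are *not* chased transitively.
    """
    partner: dict[str, set[str]] = {}
    for p in pairs:
        partner.setdefault(p.accession_a, set()).add(p.accession_b)
        partner.setdefault(p.accession_b, set()).add(p.accession_a)
    out: list[OrthoGroup] = []
    for group in groups:
        members = set(group.members)
        for m in group.members:
            members.update(partner.get(m, ()))
        genes = frozenset(node_attrs[m] for m in members)
        out.append(
            OrthoGroup(
                group_id=group.group_id,
                members=frozenset(members),
                parent_genes=genes,
                species=frozenset(s for s, _ in genes),
            )
        )
    return out


def group_by_gene(groups: Sequence[OrthoGroup]) -> list[GeneGroup]:
    """Connected components of the gene-overlap graph.

    Two orthogroups are linked when the intersection of their parent-gene
    sets is at least 50% of the smaller set.
    """
    overlap = nx.Graph()
    overlap.add_nodes_from(g.group_id for g in groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            smaller = min(len(a.parent_genes), len(b.parent_genes))
            if smaller and len(a.parent_genes & b.parent_genes) >= 0.5 * smaller:
                overlap.add_edge(a.group_id, b.group_id)
    by_id = {g.group_id: g for g in groups}
    out: list[GeneGroup] = []
    comps = sorted(nx.connected_components(overlap), key=lambda c: sorted(c))
    for i, comp in enumerate(comps):
        union: set[tuple[str, str]] = set()
        for gid in comp:
            union |= by_id[gid].parent_genes
        out.append(GeneGroup(f"GG{i:05d}", frozenset(comp), frozenset(union)))
    return out


def _group_edge_score(group: OrthoGroup, graph: nx.Graph) -> float:
    total = 0.0
    members = group.members
    for a, b, data in graph.edges(members, data=True):
        if a in members and b in members:
            total += data.get("score", 0.0)
    return total


def select_single_copy(
    groups: Sequence[OrthoGroup],
    criteria: DiversityCriteria | None,
    gene_groups: Sequence[GeneGroup],
    graph: nx.Graph,
    known_species: Iterable[str] | None = None,
) -> list[OrthoGroup]:
    """Filter to single-copy groups and pick one orthogroup per gene group.

    Groups where any species contributes two or more parent genes are
    dropped, then groups failing any diversity-set minimum, and finally
    the surviving orthogroups are ranked within each gene group by
    (species count, total edge score) with ties broken by group id.
    ``known_species`` is the species universe; criteria referencing
    species outside it are rejected.
    """
    if criteria is not None and known_species is not None:
        criteria.validate_species(known_species)
    eligible: dict[str, OrthoGroup] = {}
    for group in groups:
        species_counts: dict[str, int] = {}
        for species, _gene in group.parent_genes:
            species_counts[species] = species_counts.get(species, 0) + 1
        if any(c >= 2 for c in species_counts.values()):
            continue
        if criteria is not None and not criteria.passes(group.species):
            continue
        eligible[group.group_id] = group
    selected: list[OrthoGroup] = []
    for gene_group in gene_groups:
        candidates = [eligible[gid] for gid in gene_group.orthogroup_ids if gid in eligible]
        if not candidates:
            continue
        best = min(
            candidates,
            key=lambda g: (-len(g.species), -_group_edge_score(g, graph), g.group_id),
        )
        selected.append(best)
    return sorted(selected, key=lambda g: g.group_id)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def write_groups(path, groups: Sequence[OrthoGroup]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for group in groups:
            for member in sorted(group.members):
                writer.writerow([group.group_id, member])


def write_gene_groups(path, gene_groups: Sequence[GeneGroup]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for gg in gene_groups:
            for gid in sorted(gg.orthogroup_ids):
                writer.writerow([gg.group_id, gid])
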