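"""Planted-truth scenario generation.

Generates toy proteomes with isoforms and paralogs, homology-search
tables consistent with the planted families, block-model alignments with
planted insertions and missing segments, per-column state labels, and a
species tree — everything the downstream modules need, with the ground
truth recorded alongside.

Scores follow an identity model: bit score = identity * length * 2 plus
Gaussian noise; E-values are a deterministic decreasing function of the
bit score (only the ordering matters downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hit_processing import HSP, ProteinRecord
from .profile_weighting import write_fasta
from .trees import ArrayTree

__all__ = ["ScenarioConfig", "PlantedScenario", "generate_scenario", "ladder_newick"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class ScenarioConfig:
    n_species: int = 8
    n_genes: int = 20
    protein_length: int = 150
    n_paralog_pairs: int = 2
    n_insertions: int = 3
    insertion_length: int = 30
    n_missing: int = 2
    missing_length: int = 20
    mutation_rate: float = 0.05
    paralog_mutation_rate: float = 0.02
    noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_insertions + self.n_missing > self.n_genes * self.n_species:
            raise ValueError("more planted defects than sequences")
        if self.n_insertions + self.n_missing > self.n_genes:
            raise ValueError("defects must go to distinct genes; not enough genes")
        if self.n_paralog_pairs > self.n_genes:
            raise ValueError("more paralog pairs than genes")


@dataclass
class PlantedScenario:
    config: ScenarioConfig
    seed: int
    newick: str
    species: list[str]
    records: list[ProteinRecord]
    gene_map: dict[str, tuple[str, str]]
    truth_groups: list[frozenset[str]]
    truth_paralogs: list[tuple[str, str]]
    alignments: dict[str, dict[str, str]]  # gene key -> {accession: aligned row}
    alignment_species: dict[str, dict[str, str]]  # gene key -> {accession: species}
    insertions: list[tuple[str, str, tuple[int, int]]]
    missing: list[tuple[str, str, tuple[int, int]]]
    labels: dict[str, np.ndarray]  # gene key -> per-column insertion-state index
    inter_rows: dict[tuple[str, str], list[tuple]] = field(repr=False, default_factory=dict)
    self_rows: dict[str, list[tuple]] = field(repr=False, default_factory=dict)

    @property
    def tree(self) -> ArrayTree:
        return ArrayTree.from_newick(self.newick)

    @property
    def query_lengths(self) -> dict[str, int]:
        return {r.accession: r.length for r in self.records}

    @property
    def species_of(self) -> dict[str, str]:
        return {acc: sp for acc, (sp, _gene) in self.gene_map.items()}

    def _to_hsps(self, rows: list[tuple]) -> list[HSP]:
        out = []
        for q, t, score, evalue, qs, qe, ss, se, _ql, _sl in rows:
            out.append(
                HSP(
                    query_accession=q,
                    target_accession=t,
                    query_gene=self.gene_map[q][1],
                    target_gene=self.gene_map[t][1],
                    query_interval=(qs - 1, qe),
                    target_interval=(ss - 1, se),
                    bit_score=score,
                    e_value=evalue,
                )
            )
        return out

    def inter_hsps(self) -> list[HSP]:
        rows = []
        for pair in sorted(self.inter_rows):
            rows.extend(self.inter_rows[pair])
        return self._to_hsps(rows)

    def self_hsps(self) -> list[HSP]:
        rows = []
        for sp in sorted(self.self_rows):
            rows.extend(self.self_rows[sp])
        return self._to_hsps(rows)

    # ------------------------------------------------------------------
    def write(self, outdir) -> None:
        out = Path(outdir)
        (out / "proteins").mkdir(parents=True, exist_ok=True)
        (out / "blast").mkdir(exist_ok=True)
        (out / "alignments").mkdir(exist_ok=True)
        (out / "labels").mkdir(exist_ok=True)
        (out / "tree.nwk").write_text(self.newick + "\n")
        with open(out / "gene_map.tsv", "w") as fh:
            for acc in sorted(self.gene_map):
                sp, gene = self.gene_map[acc]
                fh.write(f"{sp}\t{gene}\t{acc}\n")
        per_species: dict[str, dict[str, str]] = {}
        for rec in self.records:
            per_species.setdefault(rec.species_id, {})[rec.accession] = rec.sequence
        for sp in sorted(per_species):
            write_fasta(out / "proteins" / f"{sp}.fasta", dict(sorted(per_species[sp].items())))
        for (a, b), rows in sorted(self.inter_rows.items()):
            with open(out / "blast" / f"{a}__{b}.tsv", "w") as fh:
                for row in rows:
                    fh.write("\t".join(_fmt(v) for v in row) + "\n")
        for sp, rows in sorted(self.self_rows.items()):
            with open(out / "blast" / f"{sp}__{sp}.tsv", "w") as fh:
                for row in rows:
                    fh.write("\t".join(_fmt(v) for v in row) + "\n")
        for gene in sorted(self.alignments):
            write_fasta(out / "alignments" / f"{gene}.fasta", dict(sorted(self.alignments[gene].items())))
        for gene in sorted(self.labels):
            with open(out / "labels" / f"{gene}.tsv", "w") as fh:
                fh.write("\n".join(str(int(s)) for s in self.labels[gene]) + "\n")
        truth = {
            "groups": [sorted(g) for g in self.truth_groups],
            "paralogs": [list(p) for p in self.truth_paralogs],
            "insertions": [[g, s, list(iv)] for g, s, iv in self.insertions],
            "missing": [[g, s, list(iv)] for g, s, iv in self.missing],
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def ladder_newick(species: list[str], branch: float = 0.1) -> str:
    tree = f"({species[0]}:{branch},{species[1]}:{branch})"
    for sp in species[2:]:
        tree = f"({tree}:{branch},{sp}:{branch})"
    return tree + ";"


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    out[mask] = AMINO_ACIDS[rng.integers(0, AMINO_ACIDS.size, mask.sum())]
    return out


def _evalue(score: float) -> float:
    return max(10.0 ** (-score / 10.0), 1e-300)


def generate_scenario(config: ScenarioConfig, seed: int) -> PlantedScenario:
    """Generate a planted scenario; same (config, seed) is bit-reproducible."""
    rng = np.random.default_rng(seed)
    species = [f"s{i + 1:02d}" for i in range(config.n_species)]
    newick = ladder_newick(species)
    length = config.protein_length

    # --- sequences ----------------------------------------------------
    gene_keys = [f"g{g:03d}" for g in range(config.n_genes)]
    paralog_genes = gene_keys[: config.n_paralog_pairs]
    paralog_hosts = {
        gene: species[int(rng.integers(0, config.n_species))] for gene in paralog_genes
    }
    sequences: dict[str, np.ndarray] = {}
    records: list[ProteinRecord] = []
    gene_map: dict[str, tuple[str, str]] = {}
    family: dict[str, list[str]] = {g: [] for g in gene_keys}
    truth_paralogs: list[tuple[str, str]] = []
    for gene in gene_keys:
        ancestor = AMINO_ACIDS[rng.integers(0, AMINO_ACIDS.size, length)]
        for sp in species:
            acc = f"{sp}_{gene}_p1"
            seq = _mutate(rng, ancestor, config.mutation_rate)
            sequences[acc] = seq
            gene_map[acc] = (sp, gene)
            family[gene].append(acc)
            records.append(ProteinRecord(acc, gene, sp, length, "".join(seq)))
        if gene in paralog_hosts:
            host = paralog_hosts[gene]
            orig = f"{host}_{gene}_p1"
            acc = f"{host}_{gene}d_p1"
            seq = _mutate(rng, sequences[orig], config.paralog_mutation_rate)
            sequences[acc] = seq
            gene_map[acc] = (host, f"{gene}d")
            family[gene].append(acc)
            records.append(ProteinRecord(acc, f"{gene}d", host, length, "".join(seq)))
            truth_paralogs.append(tuple(sorted((orig, acc))))

    # --- planted orthogroups (paralogs included) ----------------------
    truth_groups = [frozenset(family[g]) for g in gene_keys]

    # --- homology-search tables ---------------------------------------
    def identity(a: str, b: str) -> float:
        return float(np.mean(sequences[a] == sequences[b]))

    inter_rows: dict[tuple[str, str], list[tuple]] = {}
    for a in species:
        for b in species:
            if a == b:
                continue
            rows = []
            for gene in gene_keys:
                queries = [acc for acc in family[gene] if gene_map[acc][0] == a]
                targets = [acc for acc in family[gene] if gene_map[acc][0] == b]
                for q in queries:
                    for t in targets:
                        score = identity(q, t) * length * 2 + rng.normal(0, config.noise_sigma)
                        score = max(score, 25.0)
                        rows.append((q, t, score, _evalue(score), 1, length, 1, length, length, length))
            inter_rows[(a, b)] = rows
    self_rows: dict[str, list[tuple]] = {}
    for sp in species:
        rows = []
        for gene in gene_keys:
            members = [acc for acc in family[gene] if gene_map[acc][0] == sp]
            for q in members:
                for t in members:
                    ident = identity(q, t)
                    score = ident * length * 2 + (
                        0.0 if q == t else rng.normal(0, config.noise_sigma)
                    )
                    score = max(score, 25.0)
                    rows.append((q, t, score, _evalue(score), 1, length, 1, length, length, length))
        self_rows[sp] = rows

    # --- planted alignments with defects ------------------------------
    defect_genes = list(rng.permutation(gene_keys[config.n_paralog_pairs :]))
    insertion_genes = defect_genes[: config.n_insertions]
    missing_genes = defect_genes[config.n_insertions : config.n_insertions + config.n_missing]

    alignments: dict[str, dict[str, str]] = {}
    alignment_species: dict[str, dict[str, str]] = {}
    insertions: list[tuple[str, str, tuple[int, int]]] = []
    missing: list[tuple[str, str, tuple[int, int]]] = []
    labels: dict[str, np.ndarray] = {}
    for gene in gene_keys:
        rows = {
            acc: "".join(sequences[acc])
            for acc in family[gene]
            if not gene_map[acc][1].endswith("d")
        }
        label = np.zeros(length, dtype=int)
        margin = min(20, max(2, length // 6))
        if gene in insertion_genes:
            victim = sorted(rows)[int(rng.integers(0, len(rows)))]
            pos = int(rng.integers(margin, length - margin))
            insert = "".join(AMINO_ACIDS[rng.integers(0, AMINO_ACIDS.size, config.insertion_length)])
            gap = "-" * config.insertion_length
            rows = {
                acc: row[:pos] + (insert if acc == victim else gap) + row[pos:]
                for acc, row in rows.items()
            }
            label = np.concatenate([label[:pos], np.full(config.insertion_length, 3), label[pos:]])
            insertions.append((gene, victim, (pos, pos + config.insertion_length)))
        elif gene in missing_genes:
            victim = sorted(rows)[int(rng.integers(0, len(rows)))]
            hi = length - margin - config.missing_length
            if hi <= margin:
                raise ValueError("missing segment too long for protein length")
            pos = int(rng.integers(margin, hi))
            interval = (pos, pos + config.missing_length)
            rows = {
                acc: (row[: pos] + "-" * config.missing_length + row[pos + config.missing_length :])
                if acc == victim
                else row
                for acc, row in rows.items()
            }
            missing.append((gene, victim, interval))
        alignments[gene] = rows
        alignment_species[gene] = {acc: gene_map[acc][0] for acc in rows}
        labels[gene] = label

    return PlantedScenario(
        config=config,
        seed=seed,
        newick=newick,
        species=species,
        records=records,
        gene_map=gene_map,
        truth_groups=truth_groups,
        truth_paralogs=truth_paralogs,
        alignments=alignments,
        alignment_species=alignment_species,
        insertions=insertions,
        missing=missing,
        labels=labels,
        inter_rows=inter_rows,
        self_rows=self_rows,
    )
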