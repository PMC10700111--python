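import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthotrim.hit_processing import (
    HSP,
    Hit,
    ParalogPair,
    ProteinRecord,
    apply_hit_filters,
    deduplicate_proteins,
    detect_paralogs,
    extract_best_gene_hsps,
    filter_by_evalue,
    merge_hsps,
    select_best_hit,
)


def make_hsp(
    q="q1",
    t="t1",
    qgene="gq",
    tgene="gt",
    qiv=(0, 50),
    tiv=(0, 50),
    score=100.0,
    evalue=1e-30,
):
    return HSP(q, t, qgene, tgene, qiv, tiv, score, evalue)


# ----------------------------------------------------------------------
# deduplicate_proteins
# ----------------------------------------------------------------------
class TestDeduplicate:
    def test_duplicate_sequence_removed(self):
        records = [
            ProteinRecord("P1", "G", "sp", 3, "MAD"),
            ProteinRecord("P2", "G", "sp", 3, "MAD"),
            ProteinRecord("P3", "G", "sp", 4, "MADE"),
        ]
        kept = deduplicate_proteins(records)
        assert [r.accession for r in kept] == ["P1", "P3"]

    def test_single_record_identity(self):
        records = [ProteinRecord("P1", "G", "sp", 3, "MAD")]
        assert deduplicate_proteins(records) == records

    def test_shared_sequence_across_genes_retained(self):
        # Oracle: enumerate (sequence, gene) pairs; both pairs are distinct,
        # so the per-(sequence, gene) rule keeps both accessions.
        records = [
            ProteinRecord("P1", "G1", "sp", 3, "MAD"),
            ProteinRecord("P2", "G2", "sp", 3, "MAD"),
        ]
        assert len(deduplicate_proteins(records)) == 2

    def test_duplicate_accession_rejected(self):
        records = [
            ProteinRecord("P1", "G", "sp", 3, "MAD"),
            ProteinRecord("P1", "G", "sp", 4, "MADE"),
        ]
        with pytest.raises(ValueError, match="duplicate accession"):
            deduplicate_proteins(records)

    def test_same_accession_other_species_allowed(self):
        records = [
            ProteinRecord("P1", "G", "sp1", 3, "MAD"),
            ProteinRecord("P1", "G", "sp2", 3, "MAD"),
        ]
        assert len(deduplicate_proteins(records)) == 2


# ----------------------------------------------------------------------
# filter_by_evalue
# ----------------------------------------------------------------------
class TestEvalueFilter:
    def test_threshold(self):
        hsps = [make_hsp(evalue=1e-12), make_hsp(evalue=1e-5)]
        assert filter_by_evalue(hsps, 1e-10) == [hsps[0]]

    def test_empty(self):
        assert filter_by_evalue([], 1e-10) == []

    def test_boundary_inclusive(self):
        hsps = [make_hsp(evalue=1e-10)]
        assert filter_by_evalue(hsps, 1e-10) == hsps

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            filter_by_evalue([], 0.0)


# ----------------------------------------------------------------------
# extract_best_gene_hsps
# ----------------------------------------------------------------------
class TestBestGene:
    def test_stops_at_gene_change(self):
        hsps = [
            make_hsp(t="T1", tgene="gA", score=100),
            make_hsp(t="T2", tgene="gA", score=90),
            make_hsp(t="T3", tgene="gB", score=80),
        ]
        kept = extract_best_gene_hsps(hsps)
        assert {h.target_accession for h in kept} == {"T1", "T2"}

    def test_single_group(self):
        hsps = [make_hsp(t="T1", score=10), make_hsp(t="T1", score=5)]
        assert extract_best_gene_hsps(hsps) == hsps

    def test_tie_at_top(self):
        # Hand-trace: gA and gB tie at 100; iteration continues while the
        # current group's gene is one of the tied top genes, so T3 (gA)
        # is also emitted.
        hsps = [
            make_hsp(t="T1", tgene="gA", score=100),
            make_hsp(t="T2", tgene="gB", score=100),
            make_hsp(t="T3", tgene="gA", score=95),
        ]
        kept = extract_best_gene_hsps(hsps)
        assert {h.target_accession for h in kept} == {"T1", "T2", "T3"}

    def test_order_invariance(self, rng):
        hsps = [
            make_hsp(t=f"T{i}", tgene=f"g{i % 3}", score=float(s), qiv=(0, 10 + i))
            for i, s in enumerate([50, 90, 70, 90, 30, 60])
        ]
        baseline = {h.target_accession for h in extract_best_gene_hsps(hsps)}
        for _ in range(10):
            shuffled = list(hsps)
            rng.shuffle(shuffled)
            assert {h.target_accession for h in extract_best_gene_hsps(shuffled)} == baseline


# ----------------------------------------------------------------------
# merge_hsps
# ----------------------------------------------------------------------
class TestMergeHsps:
    def test_two_pass_trace(self):
        # Brute-force trace: A disjoint, C disjoint (no overlap with A),
        # B overlaps C by 40 > 25 = 50% of either -> not compatible.
        a = make_hsp(qiv=(0, 50), score=100)
        b = make_hsp(qiv=(40, 90), score=60)
        c = make_hsp(qiv=(50, 100), score=50)
        hit = merge_hsps([a, b, c], query_length=100)
        flags = {h.query_interval: (h.disjoint, h.compatible) for h in hit.hsps}
        assert flags[(0, 50)] == (True, True)
        assert flags[(50, 100)] == (True, True)
        assert flags[(40, 90)] == (False, False)
        assert hit.disjoint_score == 150
        assert hit.query_coverage == 1.0

    def test_single_hsp(self):
        hit = merge_hsps([make_hsp(score=42.0)], query_length=100)
        assert hit.hsps[0].disjoint and hit.hsps[0].compatible
        assert hit.disjoint_score == 42.0

    def test_identical_intervals_boundary(self):
        # overlap equals 100% of either interval -> second neither
        # disjoint nor compatible
        first = make_hsp(qiv=(0, 30), score=10)
        second = make_hsp(qiv=(0, 30), score=9)
        hit = merge_hsps([first, second], query_length=30)
        by_score = {h.bit_score: h for h in hit.hsps}
        assert by_score[10].disjoint
        assert not by_score[9].disjoint and not by_score[9].compatible

    def test_half_overlap_is_compatible(self):
        # overlap exactly 50% of both lengths passes the "no more than" rule
        a = make_hsp(qiv=(0, 40), score=10)
        b = make_hsp(qiv=(20, 60), score=9)
        hit = merge_hsps([a, b], query_length=60)
        assert all(h.compatible for h in hit.hsps)
        assert sum(h.disjoint for h in hit.hsps) == 1

    def test_empty(self):
        assert merge_hsps([], query_length=10) is None


def _random_hsps(rng, n, span=60):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span - 2))
        stop = int(rng.integers(start + 1, span))
        out.append(make_hsp(qiv=(start, stop), score=float(rng.integers(1, 100))))
    return out


def _brute_force_max_disjoint(hsps):
    best = 0.0
    for r in range(len(hsps) + 1):
        for combo in itertools.combinations(hsps, r):
            ok = all(
                min(a.query_interval[1], b.query_interval[1])
                <= max(a.query_interval[0], b.query_interval[0])
                for a, b in itertools.combinations(combo, 2)
            )
            if ok:
                best = max(best, sum(h.bit_score for h in combo))
    return best


class TestMergeProperties:
    def test_disjoint_pairwise_non_overlapping(self, rng):
        for _ in range(200):
            hsps = _random_hsps(rng, int(rng.integers(1, 12)))
            hit = merge_hsps(hsps, query_length=60)
            disjoint = [h for h in hit.hsps if h.disjoint]
            for a, b in itertools.combinations(disjoint, 2):
                assert (
                    min(a.query_interval[1], b.query_interval[1])
                    <= max(a.query_interval[0], b.query_interval[0])
                )

    def test_greedy_le_optimal(self, rng):
        suboptimal_seen = 0
        for _ in range(200):
            hsps = _random_hsps(rng, int(rng.integers(1, 9)))
            hit = merge_hsps(hsps, query_length=60)
            optimum = _brute_force_max_disjoint(hsps)
            assert hit.disjoint_score <= optimum + 1e-9
            if hit.disjoint_score < optimum - 1e-9:
                suboptimal_seen += 1
        # the greedy strategy is intentionally not optimal; random
        # instances where it loses to the scheduling optimum exist
        assert suboptimal_seen > 0

    def test_disjoint_score_le_total(self, rng):
        for _ in range(50):
            hsps = _random_hsps(rng, int(rng.integers(1, 10)))
            hit = merge_hsps(hsps, query_length=60)
            assert hit.disjoint_score <= sum(h.bit_score for h in hsps) + 1e-9


# ----------------------------------------------------------------------
# select_best_hit / apply_hit_filters
# ----------------------------------------------------------------------
def make_hit(q, t, score, coverage=1.0):
    return Hit(q, t, [], score, coverage)


class TestBestHit:
    def test_argmax(self):
        hits = [make_hit("q", "T1", 150), make_hit("q", "T2", 140)]
        assert select_best_hit(hits).target_accession == "T1"

    def test_single(self):
        hit = make_hit("q", "T1", 1.0)
        assert select_best_hit([hit]) is hit

    def test_tie_breaks_lexicographic(self):
        hits = [make_hit("q", "T1", 150), make_hit("q", "T0", 150)]
        assert select_best_hit(hits).target_accession == "T0"

    def test_empty(self):
        assert select_best_hit([]) is None


class TestHitFilters:
    def test_coverage_boundary(self):
        low = [make_hit("a", "b", 10, 0.49), make_hit("b", "a", 10, 1.0)]
        assert apply_hit_filters(low) == {}
        ok = [make_hit("a", "b", 10, 0.50), make_hit("b", "a", 10, 1.0)]
        assert ("a", "b") in apply_hit_filters(ok)

    def test_reciprocity_required(self):
        hits = [make_hit("q", "t", 10), make_hit("t", "u", 10)]
        assert apply_hit_filters(hits) == {}

    def test_symmetric_pair_single_edge(self):
        hits = [make_hit("q", "t", 10), make_hit("t", "q", 12)]
        edges = apply_hit_filters(hits)
        assert edges == {("q", "t"): 12}

    def test_symmetry_property(self, rng):
        names = [f"x{i}" for i in range(8)]
        hits = []
        for q in names:
            t = names[int(rng.integers(0, len(names)))]
            if t != q:
                hits.append(make_hit(q, t, float(rng.integers(1, 50)), float(rng.random())))
        edges = apply_hit_filters(hits)
        for a, b in edges:
            assert a < b  # canonical order: symmetric relation stored once
            assert a != b


class TestDetectParalogs:
    def test_emitted_above_ceiling(self):
        hits = [make_hit("q", "t", 200, 0.9), make_hit("t", "q", 195, 0.9)]
        pairs = detect_paralogs(hits, {"q": 180, "t": 180})
        assert [(p.accession_a, p.accession_b) for p in pairs] == [("q", "t")]

    def test_equal_score_not_emitted(self):
        hits = [make_hit("q", "t", 180, 0.9), make_hit("t", "q", 170, 0.9)]
        assert detect_paralogs(hits, {"q": 180, "t": 180}) == []

    def test_no_inter_genome_hits_is_minus_inf(self):
        hits = [make_hit("q", "t", 5, 0.9), make_hit("t", "q", 5, 0.9)]
        pairs = detect_paralogs(hits, {})
        assert len(pairs) == 1

    def test_self_match_excluded(self):
        hits = [make_hit("q", "q", 1000, 1.0)]
        assert detect_paralogs(hits, {}) == []

    def test_reciprocity_required(self):
        hits = [make_hit("q", "t", 200, 0.9)]
        assert detect_paralogs(hits, {}) == []


@given(
    st.lists(
        st.tuples(st.integers(0, 40), st.integers(1, 20), st.integers(1, 100)),
        min_size=1,
        max_size=10,
    )
)
@settings(max_examples=50, deadline=None)
def test_merge_hsps_hypothesis(intervals):
    hsps = [
        make_hsp(qiv=(s, s + w), score=float(sc)) for s, w, sc in intervals
    ]
    hit = merge_hsps(hsps, query_length=80)
    disjoint = [h for h in hit.hsps if h.disjoint]
    assert all(h.compatible for h in disjoint)
    for a, b in itertools.combinations(disjoint, 2):
        assert (
            min(a.query_interval[1], b.query_interval[1])
            <= max(a.query_interval[0], b.query_interval[0])
        )
    assert 0.0 <= hit.query_coverage <= 1.0
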