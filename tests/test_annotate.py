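"""Seed-and-extend annotation: anchors, extension, filters, hit merging."""

import numpy as np
import pytest
from Bio import Align

from tepoly._align import revcomp
from tepoly.annotate import (
    Anchor,
    RepeatHit,
    annotate_sequence,
    extend_hit,
    filter_hits,
    hits_mergeable,
    merge_split_hits,
    seed_matches,
)
from tepoly.library import TEConsensus

from conftest import random_seq, with_substitutions


def _sw_identity(a: str, b: str) -> float:
    """Full Smith-Waterman oracle identity (matches / aligned non-gap cols)."""
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 1
    al.mismatch_score = -2
    al.open_gap_score = -5
    al.extend_gap_score = -1
    best = al.align(a, b)[0]
    c = best.counts()
    return c.identities / (c.identities + c.mismatches)


class TestSeeds:
    def test_exact_substring_yields_all_anchors(self, rng, small_library):
        cons = small_library[0]
        seq = random_seq(rng, 200) + cons.sequence[300:340] + random_seq(rng, 200)
        anchors = seed_matches(seq, [cons], k=12)
        plus = [a for a in anchors if a.strand == "+" and a.consensus_id == "CR1-X"]
        assert len(plus) >= 40 - 12 + 1

    def test_reverse_complement_anchors_minus(self, rng, small_library):
        cons = small_library[0]
        seq = random_seq(rng, 100) + revcomp(cons.sequence[300:340]) + random_seq(rng, 100)
        anchors = seed_matches(seq, [cons], k=12)
        assert anchors and all(a.strand == "-" for a in anchors)

    def test_no_shared_kmer_empty(self, rng, small_library):
        # oracle: exhaustive 12-mer set intersection
        k = 12
        while True:
            seq = random_seq(rng, 150)
            seq_kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
            lib_kmers = set()
            for c in small_library:
                for s in (c.sequence, revcomp(c.sequence)):
                    lib_kmers |= {s[i : i + k] for i in range(len(s) - k + 1)}
            if not seq_kmers & lib_kmers:
                break
        assert seed_matches(seq, small_library, k=k) == []

    def test_k_out_of_range(self, small_library):
        with pytest.raises(ValueError):
            seed_matches("ACGT" * 50, small_library, k=4)


class TestExtend:
    def test_exact_copy_full_recovery(self, rng, small_library):
        cons = small_library[0]
        copy = cons.sequence[200:700]
        seq = random_seq(rng, 400) + copy + random_seq(rng, 400)
        hit = extend_hit(Anchor(400 + 250, cons.id, 450, "+"), seq, cons)
        assert hit.identity == 1.0
        assert hit.start <= 400 and hit.end >= 900
        assert hit.end - hit.start <= 510  # no runaway extension

    def test_divergent_copy_identity_matches_sw_oracle(self, rng, small_library):
        cons = small_library[0]
        copy = with_substitutions(cons.sequence[100:600], 0.10, rng)
        seq = random_seq(rng, 300) + copy + random_seq(rng, 300)
        # anchor on an exact 12-mer inside the copy
        gpos = next(
            300 + i
            for i in range(0, 480)
            if copy[i : i + 12] == cons.sequence[100 + i : 112 + i]
        )
        hit = extend_hit(Anchor(gpos, cons.id, gpos - 300 + 100, "+"), seq, cons)
        assert abs(hit.divergence - 0.10) <= 0.02
        oracle = _sw_identity(copy, cons.sequence[100:600])
        assert abs(hit.identity - oracle) <= 0.02

    def test_score_at_least_seed(self, rng, small_library):
        cons = small_library[0]
        seq = random_seq(rng, 300) + cons.sequence[500:540] + random_seq(rng, 300)
        hit = extend_hit(Anchor(310, cons.id, 510, "+"), seq, cons, k=12)
        assert hit.score >= 12  # seed score with +1 match


class TestFilter:
    def _hit(self, length, div):
        return RepeatHit("s", 0, length, "+", "CR1-X", 0, length, 1 - div, 10)

    def test_length_boundary_exclusive_below(self):
        assert filter_hits([self._hit(99, 0.05)]) == []

    def test_inclusive_boundaries_retained(self):
        kept = filter_hits([self._hit(100, 0.20)])
        assert len(kept) == 1

    def test_empty_input(self):
        assert filter_hits([]) == []


class TestMerge:
    def _hit(self, s, e, cid, cs, ce, strand="+"):
        return RepeatHit("s", s, e, strand, cid, cs, ce, 0.95, e - s)

    def test_contiguous_parts_merge(self):
        hits = [self._hit(0, 500, "CR1-X", 0, 500), self._hit(800, 1320, "CR1-X", 480, 1000)]
        merged = merge_split_hits(hits)
        assert len(merged) == 1 and len(merged[0].components) == 2
        assert merged[0].span == (0, 1320)

    def test_different_consensi_stay_separate(self):
        hits = [self._hit(0, 500, "CR1-X", 0, 500), self._hit(600, 1100, "L1-Y", 0, 500)]
        assert len(merge_split_hits(hits)) == 2

    def test_transitive_closure_matches_bruteforce(self, rng):
        hits = []
        pos = 0
        for _ in range(5):
            ln = int(rng.integers(150, 400))
            cs = int(rng.integers(0, 800))
            hits.append(self._hit(pos, pos + ln, "CR1-X", cs, cs + ln))
            pos += ln + int(rng.integers(10, 2000))
        merged = merge_split_hits(hits)
        # brute-force transitive closure over the pairwise predicate
        n = len(hits)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            adj[i, i] = True
            for j in range(n):
                if i != j and hits_mergeable(hits[i], hits[j]):
                    adj[i, j] = adj[j, i] = True
        for _ in range(n):
            adj = adj | (adj @ adj)
        n_groups = len({tuple(row) for row in adj})
        assert len(merged) == n_groups

    def test_no_hit_lost_or_duplicated(self, rng):
        hits = []
        for _ in range(20):
            s = int(rng.integers(0, 50000))
            ln = int(rng.integers(100, 500))
            cs = int(rng.integers(0, 1500))
            cid = ["CR1-X", "L1-Y"][int(rng.integers(2))]
            hits.append(self._hit(s, s + ln, cid, cs, cs + ln))
        merged = merge_split_hits(hits)
        assert sum(len(m.components) for m in merged) == len(hits)


def test_zero_substitution_simulation_full_recall():
    """Planted TEs >= 100 nt are each recovered as exactly one insertion with
    divergence 0 when the genomes carry no mutations at all."""
    from tepoly.simulate import SimulationConfig, simulate_pair

    cfg = SimulationConfig(
        seed=5,
        ancestor_length=60_000,
        substitution_rate=0.0,
        small_indel_rate=0.0,
        shared_te_density=100.0,
        shared_divergence_range=(0.0, 0.0),
        specific_te_count=5,
        specific_divergence_range=(0.0, 0.0),
        n_stretch_count=0,
        composite_count=0,
        erv=__import__("tepoly.simulate", fromlist=["ErvSpec"]).ErvSpec(
            recombination=False, element_divergence=0.0
        ),
    )
    sim = simulate_pair(cfg)
    annots = annotate_sequence(sim.genome_a, sim.library, seq_id="genomeA")
    planted = [
        e.a_element
        for e in sim.manifest.events
        if e.a_element and (e.a_element[1] - e.a_element[0]) >= 100
    ]
    for s, e in planted:
        # 10 nt slack: poly-A tails on LINE plants are part of the planted
        # element but not of the consensus, so annotation stops before them
        covering = [a for a in annots if a.start <= s + 10 and a.end >= e - 10]
        assert len(covering) == 1, (s, e)
        assert covering[0].divergence <= 1e-9
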