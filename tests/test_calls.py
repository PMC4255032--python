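"""Face-to-face pairing, boundary refinement, artifact screening, counting."""

import numpy as np
import pytest

from tepoly.annotate import RepeatHit, AnnotatedInsertion
from tepoly.calls import (
    SharedInsertionPair,
    count_shared,
    is_assembly_artifact,
    pair_annotations,
    refine_boundaries,
)
from tepoly.orthomap import map_genomes

from conftest import random_seq, with_substitutions


def _annot(seq_id, s, e, superfamily="CR1", eid=1, cid="CR1-X"):
    hit = RepeatHit(seq_id, s, e, "+", cid, 0, e - s, 0.98, float(e - s))
    return AnnotatedInsertion(element_id=eid, seq_id=seq_id, components=[hit],
                              superfamily=superfamily)


def _identity_fragments(rng, n=20_000):
    a = random_seq(rng, n)
    b = with_substitutions(a, 0.013, rng)
    frags = map_genomes(a, b, a_seq_id="A", b_seq_id="B")
    return a, b, frags


class TestPairing:
    def test_homologous_insertions_pair_as_shared(self, rng):
        a, b, frags = _identity_fragments(rng)
        shared, ua, ub, xa, xb = pair_annotations(
            [_annot("A", 5000, 5400)], [_annot("B", 5000, 5400)], frags
        )
        assert len(shared) == 1 and not ua and not ub

    def test_single_species_insertion_is_candidate(self, rng):
        a, b, frags = _identity_fragments(rng)
        shared, ua, ub, xa, xb = pair_annotations(
            [_annot("A", 5000, 5400)], [], frags
        )
        assert not shared and len(ua) == 1

    def test_superfamily_mismatch_blocks_pairing(self, rng):
        a, b, frags = _identity_fragments(rng)
        shared, ua, ub, xa, xb = pair_annotations(
            [_annot("A", 5000, 5400, "CR1")],
            [_annot("B", 5000, 5400, "Gypsy")],
            frags,
        )
        assert not shared and len(ua) == 1 and len(ub) == 1

    def test_greedy_matches_bruteforce_optimal_on_nested(self, rng):
        # two nested A insertions over one B insertion: greedy 1-to-1 keeps
        # the highest-overlap pair, which equals the optimal matching here
        a, b, frags = _identity_fragments(rng)
        annots_a = [
            _annot("A", 5000, 5600, eid=1),
            _annot("A", 5100, 5500, eid=2),
        ]
        annots_b = [_annot("B", 5000, 5600, eid=3)]
        shared, ua, ub, xa, xb = pair_annotations(annots_a, annots_b, frags)
        assert len(shared) == 1
        assert shared[0].insertion_a.element_id == 1  # maximal reciprocal overlap
        assert len(ua) == 1 and ua[0].element_id == 2

    def test_annotation_outside_fragments_excluded(self, rng, caplog):
        a, b, frags = _identity_fragments(rng, n=5_000)
        with caplog.at_level("WARNING"):
            shared, ua, ub, xa, xb = pair_annotations(
                [_annot("A", 100_000, 100_400)], [], frags
            )
        assert xa and not ua and "outside orthologous fragments" in caplog.text


class TestRefine:
    def test_forced_gap_block(self):
        filled = "AAAA" + "T" * 10 + "GGGG"
        empty = "AAAAGGGG"
        res = refine_boundaries(filled, empty, flank=4, min_len=8)
        assert res is not None
        assert res.interval == (4, 14)

    def test_identical_windows_rejected(self, rng):
        w = random_seq(rng, 800)
        assert refine_boundaries(w, w) is None

    def test_planted_insertion_boundaries_within_5nt(self, rng):
        flank_l = random_seq(rng, 600)
        flank_r = random_seq(rng, 600)
        ins = random_seq(rng, 1000)
        filled = flank_l + ins + flank_r
        empty = with_substitutions(flank_l + flank_r, 0.013, rng)
        res = refine_boundaries(filled, empty)
        assert res is not None and res.refined
        s, e = res.interval
        assert abs(s - 600) <= 5 and abs(e - 1600) <= 5

    def test_flank_identity_agrees_with_edlib_oracle(self, rng):
        # unit-cost full-DP identity of the two flanks as the oracle
        import edlib

        flank_l = random_seq(rng, 500)
        flank_r = random_seq(rng, 500)
        ins = random_seq(rng, 400)
        empty_l = with_substitutions(flank_l, 0.02, rng)
        empty_r = with_substitutions(flank_r, 0.02, rng)
        res = refine_boundaries(flank_l + ins + flank_r, empty_l + empty_r)
        assert res is not None

        def oracle(x, y):
            r = edlib.align(x, y, task="path")
            eq = x_ = 0
            n = 0
            for ch in r["cigar"]:
                if ch.isdigit():
                    n = n * 10 + int(ch)
                else:
                    if ch == "=":
                        eq += n
                    elif ch == "X":
                        x_ += n
                    n = 0
            return eq / (eq + x_)

        assert abs(res.flank_identity_left - oracle(flank_l, empty_l)) <= 0.02
        assert abs(res.flank_identity_right - oracle(flank_r, empty_r)) <= 0.02


class TestArtifacts:
    def test_matching_n_stretch_is_artifact(self, rng):
        window = random_seq(rng, 300) + "N" * 1000 + random_seq(rng, 300)
        flag, iv = is_assembly_artifact(window, 1000)
        assert flag and iv == (300, 1300)

    def test_no_n_not_artifact(self, rng):
        flag, _ = is_assembly_artifact(random_seq(rng, 1500), 1000)
        assert not flag

    def test_length_mismatch_not_artifact(self, rng):
        window = random_seq(rng, 300) + "N" * 400 + random_seq(rng, 300)
        flag, _ = is_assembly_artifact(window, 1000)
        assert not flag


class TestCounting:
    def test_per_superfamily_counts(self):
        pairs = [
            SharedInsertionPair(_annot("A", 0, 100, "CR1"), _annot("B", 0, 100, "CR1"), 1.0)
            for _ in range(3)
        ] + [
            SharedInsertionPair(_annot("A", 0, 100, "Gypsy"), _annot("B", 0, 100, "Gypsy"), 1.0)
        ]
        assert count_shared(pairs) == {"CR1": 3, "Gypsy": 1, "total": 4}

    def test_empty(self):
        assert count_shared([]) == {"total": 0}

    def test_simulated_shared_counts_match_manifest(self):
        from tepoly.simulate import SimulationConfig, simulate_pair, ErvSpec
        from tepoly.pipeline import run_pair

        cfg = SimulationConfig(
            seed=11, ancestor_length=120_000, substitution_rate=0.0,
            small_indel_rate=0.0, shared_te_density=200.0,
            shared_divergence_range=(0.0, 0.0), specific_te_count=5,
            specific_divergence_range=(0.0, 0.0), n_stretch_count=0,
            composite_count=0, erv=ErvSpec(recombination=False),
        )
        sim = simulate_pair(cfg)
        res = run_pair(sim.genome_a, sim.genome_b, sim.library)
        truth = {}
        for e in sim.manifest.of_type("shared"):
            if (e.a_element[1] - e.a_element[0]) >= 100:
                truth[e.superfamily] = truth.get(e.superfamily, 0) + 1
        counts = count_shared(res.callset.shared)
        for fam, n in truth.items():
            assert counts.get(fam, 0) == n, fam


def test_full_accounting_invariant():
    """shared*2 + specific + artifact + rejected + excluded covers every
    annotated insertion."""
    from tepoly.simulate import SimulationConfig, simulate_pair
    from tepoly.pipeline import run_pair

    cfg = SimulationConfig(seed=9, ancestor_length=120_000, specific_te_count=10,
                           n_stretch_count=3)
    sim = simulate_pair(cfg)
    res = run_pair(sim.genome_a, sim.genome_b, sim.library)
    acc = res.callset.accounting()
    assert acc["total_annotations"] == len(res.annots_a) + len(res.annots_b)
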