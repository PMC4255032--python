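"""TSDs, LTR/TIR detection, solo-LTR events, composites, copy number,
expression hits and subfamily clustering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tepoly._align import global_identity, revcomp
from tepoly.features import (
    call_solo_ltr,
    cluster_subfamily,
    copy_number,
    decompose_composite,
    detect_ltrs,
    detect_tirs,
    expression_hits,
    find_tsd,
    tsd_for_indel,
)
from tepoly.library import TEConsensus

from conftest import random_seq, with_substitutions


class TestTSD:
    def test_planted_duplication_found(self):
        res = find_tsd("CCTGAGAT", "AGATGGTC")
        assert (res.sequence, res.length, res.tsd_class) == ("AGAT", 4, "TSD")

    def test_no_duplication_not_detected(self):
        res = find_tsd("GCGC", "TTAA")
        assert res.tsd_class == "not_detected" and res.sequence == ""

    def test_longest_wins_vs_exhaustive(self, rng):
        left = random_seq(rng, 30) + "ATTG"
        right = "ATTG" + random_seq(rng, 30)
        res = find_tsd(left, right)
        # oracle: exhaustive search over all suffix-prefix pairs
        best = max(
            (t for t in range(2, 26) if left[-t:] == right[:t]),
            default=0,
        )
        assert res.length == best == 4
        assert res.sequence == "ATTG"

    def test_polya_classification(self):
        res = find_tsd("G" * 10 + "A" * 20, "GCTTCGATCGGTAACCGGTT")
        assert res.tsd_class == "polyA_region"

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_outer_flank_extension(self, seed):
        rng = np.random.default_rng(seed)
        left = random_seq(rng, 30)
        right = left[-4:] + random_seq(rng, 26)  # guaranteed 4-mer duplication
        base = find_tsd(left, right)
        extended = find_tsd(random_seq(rng, 40) + left, right + random_seq(rng, 40))
        assert (base.sequence, base.tsd_class) == (extended.sequence, extended.tsd_class)

    def test_indel_slide_recovery(self, rng):
        # gap placed at either end of the target-site repeat finds the same TSD
        flank_l = random_seq(rng, 50)
        flank_r = random_seq(rng, 50)
        tsd = "AGAT"
        elem = "C" + random_seq(rng, 200) + "G"
        genome = flank_l + tsd + elem + tsd + flank_r
        s0 = len(flank_l) + len(tsd)
        # rightmost placement: gap covers element + trailing TSD
        t1 = tsd_for_indel(genome, s0, s0 + len(elem) + 4)
        # leftmost placement: gap covers leading TSD + element
        t2 = tsd_for_indel(genome, s0 - 4, s0 + len(elem))
        assert t1[0] == t2[0] == tsd


class TestLTR:
    def _element(self, rng, ltr_len=300, core_len=2000):
        ltr = random_seq(rng, ltr_len)
        return ltr + random_seq(rng, core_len) + ltr, ltr

    def test_identical_ltrs_detected(self, rng):
        elem, ltr = self._element(rng)
        pair = detect_ltrs(elem)
        assert pair is not None and pair.identity == 1.0
        assert pair.length == pytest.approx(300, abs=5)
        assert pair.left_interval[0] <= 5 and pair.right_interval[1] >= len(elem) - 5

    def test_diverged_ltr_identity_matches_full_dp_oracle(self, rng):
        ltr = random_seq(rng, 300)
        ltr2 = list(ltr)
        for p in rng.choice(300, size=6, replace=False):
            ltr2[p] = "ACGT"[("ACGT".index(ltr2[p]) + 1) % 4]
        ltr2 = "".join(ltr2)
        elem = ltr + random_seq(rng, 2000) + ltr2
        pair = detect_ltrs(elem)
        assert pair is not None
        oracle = global_identity(ltr, ltr2)  # edlib unit-cost full DP
        assert abs(pair.identity - oracle) <= 0.02
        assert pair.identity == pytest.approx(0.98, abs=0.01)

    def test_shuffled_sequence_no_ltr(self, rng):
        assert detect_ltrs(random_seq(rng, 2000)) is None

    def test_tir_detection_on_mite_structure(self, rng):
        tir = random_seq(rng, 25)
        elem = tir + random_seq(rng, 180) + revcomp(tir)
        pair = detect_tirs(elem)
        assert pair is not None and pair.kind == "TIR"
        assert pair.identity == 1.0


class TestSoloLTR:
    def _setup(self, rng):
        ltr = random_seq(rng, 462)
        core = random_seq(rng, 4000)
        tsd = "AGAT"
        elem = ltr + core + ltr
        flank_l = random_seq(rng, 300)
        flank_r = random_seq(rng, 300)
        empty = flank_l + tsd + with_substitutions(ltr, 0.01, rng) + tsd + flank_r
        return elem, tsd, empty

    class _Call:
        def __init__(self, tsd):
            self.tsd = tsd

    def test_programmed_recombination_site_detected(self, rng):
        elem, tsd, empty = self._setup(rng)
        pair = detect_ltrs(elem)
        ev = call_solo_ltr(self._Call(tsd), pair, elem, empty)
        assert ev is not None
        assert ev.shared_tsd == "AGAT"
        assert ev.ltr_identity_to_solo >= 0.98

    def test_unrelated_site_rejected(self, rng):
        elem, tsd, _ = self._setup(rng)
        pair = detect_ltrs(elem)
        decoy = random_seq(rng, 300) + tsd + random_seq(rng, 462) + tsd + random_seq(rng, 300)
        assert call_solo_ltr(self._Call(tsd), pair, elem, decoy) is None

    def test_tsd_mismatch_rejected(self, rng):
        elem, tsd, empty = self._setup(rng)
        pair = detect_ltrs(elem)
        assert call_solo_ltr(self._Call("CCCC"), pair, elem, empty) is None


class TestComposite:
    def test_three_component_concatenation(self, rng, small_library):
        sine = small_library[2]
        other = TEConsensus("SINE-W", "SINE", random_seq(rng, 280))
        ins = sine.sequence + other.sequence + sine.sequence
        dec = decompose_composite(ins, [sine, other])
        assert [c[0] for c in dec.components] == ["SINE-Z", "SINE-W", "SINE-Z"]
        assert len({c[2] for c in dec.components}) == 1  # same strand
        assert not dec.partial

    def test_single_family_degenerate(self, rng, small_library):
        sine = small_library[2]
        dec = decompose_composite(sine.sequence, small_library)
        assert len(dec.components) == 1 and dec.components[0][0] == "SINE-Z"

    def test_greedy_tiling_near_optimal(self, rng, small_library):
        # exhaustive search over subsets of candidate hits as the oracle
        pieces = [small_library[2].sequence[:150], small_library[1].sequence[:200],
                  small_library[0].sequence[:180]]
        ins = "".join(pieces)
        dec = decompose_composite(ins, small_library, min_component_len=100)
        coverage = sum(e - s for _, (s, e), _, _ in dec.components)
        assert coverage >= 0.9 * len(ins)


class TestCopyNumber:
    def test_planted_copies_counted(self, rng, small_library):
        q = small_library[2].sequence  # 300 nt
        target = (
            random_seq(rng, 500) + q + random_seq(rng, 500) + q
            + random_seq(rng, 500) + q + random_seq(rng, 300)
            + q[: int(0.7 * len(q))] + random_seq(rng, 500)
        )
        assert copy_number(q, [target]) == (3, 3)

    def test_query_only_at_own_locus(self, rng):
        q = random_seq(rng, 400)
        target = random_seq(rng, 2000) + q + random_seq(rng, 2000)
        assert copy_number(q, [target]) == (1, 1)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            copy_number("ACGT" * 10, ["ACGT" * 100])

    def test_monotone_in_identity_and_length(self, rng):
        q = random_seq(rng, 300)
        copies = [with_substitutions(q, d, rng) for d in (0.0, 0.05, 0.1, 0.15)]
        target = random_seq(rng, 200).join([""] + copies + [""])
        n1, _ = copy_number(q, [target], min_identity=0.80)
        n2, _ = copy_number(q, [target], min_identity=0.90)
        n3, _ = copy_number(q, [target], min_identity=0.80, min_len_frac=0.95)
        assert n1 >= n2
        assert n1 >= n3


class TestExpression:
    def test_embedded_fragments_counted_per_transcript(self, rng):
        q = random_seq(rng, 500)
        t1 = random_seq(rng, 100) + q[100:200] + random_seq(rng, 100)
        t2 = random_seq(rng, 50) + q[300:450] + random_seq(rng, 60)
        t3 = random_seq(rng, 300)
        assert expression_hits(q, [t1, t2, t3]) == 2

    def test_hit_below_80nt_not_counted(self, rng):
        q = random_seq(rng, 500)
        t = random_seq(rng, 100) + q[100:179] + random_seq(rng, 100)
        assert expression_hits(q, [t]) == 0


class TestClustering:
    def test_identical_sequences_one_cluster(self, rng):
        s = random_seq(rng, 400)
        clusters, mat = cluster_subfamily([s, s, s])
        assert len(clusters) == 1 and sorted(clusters[0]) == [0, 1, 2]

    def test_single_linkage_chains(self, rng):
        a = random_seq(rng, 500)
        b = with_substitutions(a, 0.01, rng)
        c = with_substitutions(b, 0.01, rng)
        # a-b and b-c ~0.99, a-c ~0.98-0.99 -> one cluster through b
        clusters, mat = cluster_subfamily([a, b, c])
        assert len(clusters) == 1
        # oracle: brute-force single linkage from the emitted matrix
        assert mat.loc[0, 1] >= 0.98 and mat.loc[1, 2] >= 0.98

    def test_divergent_sequences_singletons(self, rng):
        seqs = [random_seq(rng, 300) for _ in range(3)]
        clusters, _ = cluster_subfamily(seqs)
        assert len(clusters) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_subfamily([])
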