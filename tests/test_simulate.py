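"""Synthetic genome-pair generator: determinism, planted structure, manifest."""

import numpy as np
import pytest

from tepoly._align import global_identity
from tepoly.simulate import (
    ErvSpec,
    SimulationConfig,
    default_library,
    plant_insertion,
    read_truth,
    simulate_ancestor,
    simulate_pair,
    write_truth,
)


class TestAncestor:
    def test_determinism(self):
        cfg = SimulationConfig(seed=1, ancestor_length=100_000)
        assert simulate_ancestor(cfg) == simulate_ancestor(cfg)

    def test_gc_extreme(self):
        cfg = SimulationConfig(seed=2, ancestor_length=5_000, gc=1.0)
        assert set(simulate_ancestor(cfg)) <= {"G", "C"}

    def test_gc_within_binomial_ci(self):
        cfg = SimulationConfig(seed=3, ancestor_length=1_000_000, gc=0.5)
        seq = simulate_ancestor(cfg)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) <= 0.002


class TestPlantInsertion:
    def test_full_length_with_tsd(self, rng):
        lib = default_library()
        sine = next(c for c in lib if c.id == "LF-SINE")
        seq = simulate_ancestor(SimulationConfig(seed=4, ancestor_length=5_000))
        new, ev = plant_insertion(seq, sine, 2_000, 4, 0.0, 0.0, rng)
        s, e = ev.a_interval
        assert len(new) == len(seq) + len(sine.sequence) + 4
        # flanks of the element share the recorded 4-mer
        es, ee = ev.a_element
        assert new[es - 4 : es] == ev.tsd == new[ee : ee + 4]
        # element aligns to the consensus at identity ~1 (guard bases aside)
        assert global_identity(new[es:ee], sine.sequence) >= 0.99

    def test_truncation_keeps_3prime_half(self, rng):
        lib = default_library()
        cr1 = next(c for c in lib if c.id == "CR1-Coe")
        seq = simulate_ancestor(SimulationConfig(seed=5, ancestor_length=5_000))
        new, ev = plant_insertion(seq, cr1, 2_000, 4, 0.5, 0.0, rng)
        es, ee = ev.a_element
        planted = new[es:ee]
        assert len(planted) == len(cr1.sequence) - int(0.5 * len(cr1.sequence))
        assert global_identity(planted, cr1.sequence[len(cr1.sequence) // 2 :]) >= 0.99

    def test_divergence_realized_within_tolerance(self, rng):
        lib = default_library()
        cr1 = next(c for c in lib if c.id == "CR1-Coe")
        seq = simulate_ancestor(SimulationConfig(seed=6, ancestor_length=5_000))
        new, ev = plant_insertion(seq, cr1, 2_000, 4, 0.0, 0.10, rng)
        es, ee = ev.a_element
        ident = global_identity(new[es:ee], cr1.sequence)
        assert abs(ident - 0.90) <= 0.02
        assert abs(ev.divergence - 0.10) <= 0.02

    def test_position_out_of_range(self, rng):
        lib = default_library()
        seq = "ACGT" * 100
        with pytest.raises(ValueError):
            plant_insertion(seq, lib[0], 10**6, 4, 0.0, 0.0, rng)


class TestSpeciation:
    def test_no_mutation_no_specific_identical_genomes(self):
        cfg = SimulationConfig(
            seed=7, ancestor_length=50_000, substitution_rate=0.0,
            small_indel_rate=0.0, shared_te_density=100.0,
            shared_divergence_range=(0.0, 0.0), specific_te_count=0,
            n_stretch_count=0, composite_count=0,
            erv=ErvSpec(recombination=False),
        )
        sim = simulate_pair(cfg)
        assert sim.genome_a == sim.genome_b

    def test_specific_event_counts_match_config(self):
        cfg = SimulationConfig(seed=8, ancestor_length=150_000, specific_te_count=20,
                               n_stretch_count=2)
        sim = simulate_pair(cfg)
        assert len(sim.manifest.of_type("specific_A")) == 20
        assert len(sim.manifest.of_type("specific_B")) == 20
        assert len(sim.manifest.of_type("n_artifact")) == 2
        assert len(sim.manifest.of_type("solo_ltr_recombination")) == 1

    def test_pairwise_identity_in_flank_regions(self):
        cfg = SimulationConfig(
            seed=9, ancestor_length=400_000, substitution_rate=0.013,
            small_indel_rate=0.0, shared_te_density=0.0, specific_te_count=0,
            n_stretch_count=0, composite_count=0, erv=ErvSpec(recombination=False),
        )
        sim = simulate_pair(cfg)
        assert len(sim.genome_a) == len(sim.genome_b)
        diffs = sum(x != y for x, y in zip(sim.genome_a, sim.genome_b))
        identity = 1 - diffs / len(sim.genome_a)
        assert abs(identity - 0.987) <= 0.001

    def test_overcrowded_config_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SimulationConfig(seed=1, ancestor_length=20_000,
                             specific_te_count=100).validate()


class TestManifest:
    def test_roundtrip(self, tmp_path):
        sim = simulate_pair(SimulationConfig(seed=10, ancestor_length=80_000,
                                             specific_te_count=5, n_stretch_count=2))
        path = tmp_path / "truth.json"
        write_truth(sim.manifest, path)
        back = read_truth(path)
        assert back.seed == sim.manifest.seed
        assert len(back.events) == len(sim.manifest.events)
        assert [e.event_type for e in back.events] == [
            e.event_type for e in sim.manifest.events
        ]

    def test_empty_manifest_roundtrip(self, tmp_path):
        from tepoly.simulate import TruthManifest

        path = tmp_path / "empty.json"
        write_truth(TruthManifest(seed=0), path)
        assert read_truth(path).events == []

    def test_bad_coordinate_rejected(self, tmp_path):
        import json

        sim = simulate_pair(SimulationConfig(seed=10, ancestor_length=80_000,
                                             specific_te_count=5, n_stretch_count=0))
        path = tmp_path / "truth.json"
        write_truth(sim.manifest, path)
        data = json.loads(path.read_text())
        data["events"][0]["a_interval"] = [5, 2]
        path.write_text(json.dumps(data))
        with pytest.raises(ValueError, match="event 0"):
            read_truth(path)

    def test_manifest_coordinates_index_planted_structure(self):
        """Every specific event's TSD copies flank the recorded element."""
        sim = simulate_pair(SimulationConfig(seed=12, ancestor_length=150_000,
                                             specific_te_count=15, n_stretch_count=3))
        for ev in sim.manifest.of_type("specific_A", "specific_B"):
            genome = sim.genome_a if ev.event_type == "specific_A" else sim.genome_b
            iv = ev.a_interval if ev.event_type == "specific_A" else ev.b_interval
            el = ev.a_element if ev.event_type == "specific_A" else ev.b_element
            if ev.tsd:
                t = len(ev.tsd)
                assert genome[iv[0] : iv[0] + t] == ev.tsd  # leading copy
                assert genome[el[1] : el[1] + t] == ev.tsd  # target-site copy


def test_identical_seeds_identical_outputs():
    cfg = dict(ancestor_length=100_000, specific_te_count=10, n_stretch_count=2)
    s1 = simulate_pair(SimulationConfig(seed=77, **cfg))
    s2 = simulate_pair(SimulationConfig(seed=77, **cfg))
    assert s1.genome_a == s2.genome_a and s1.genome_b == s2.genome_b
    assert [e.__dict__ for e in s1.manifest.events] == [
        e.__dict__ for e in s2.manifest.events
    ]
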