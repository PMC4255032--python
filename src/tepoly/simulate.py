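"""Synthetic genome pairs with planted, manifest-recorded TE events.

The generator emulates the statistical structure of a comparison between two
closely related genomes: a common ancestor carrying old, diverged shared TE
copies at a configurable density; two descendant genomes separated by a
configurable pairwise substitution (and small-indel) rate; young
species-specific insertions planted after the split, framed by exact target
site duplications, with 5'-truncated LINE copies; an endogenous retrovirus
whose orthologous site carries a solo LTR produced by programmed
recombination between the element's two LTRs; assembly N-stretches that
mimic insertions in the other genome; and optional composite insertions.

Genomes are assembled from segment lists so that every planted event's final
coordinates are exact by construction; a :class:`TruthManifest` records each
event for recall/precision scoring of the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._align import revcomp
from .library import TEConsensus

BASES = np.array(list("ACGT"))

_LIBRARY_SEED = 20140912  # library content is fixed across simulation seeds


@dataclass
class ErvSpec:
    ltr_length: int = 462
    core_length: int = 4167
    element_divergence: float = 0.005  # per-copy substitutions; sets LTR-LTR identity
    tsd_length: int = 4
    recombination: bool = True


@dataclass
class SimulationConfig:
    """Study conditions of a simulated two-genome comparison."""

    seed: int
    ancestor_length: int = 1_000_000
    gc: float = 0.42
    substitution_rate: float = 0.013  # pairwise; each lineage receives half
    small_indel_rate: float = 0.0013  # pairwise; indel lengths geometric, mean 3
    indel_mean_len: float = 3.0
    shared_te_density: float = 540.0  # per Mb
    shared_divergence_range: tuple[float, float] = (0.02, 0.18)
    shared_len_log_mean: float = math.log(250.0)
    shared_len_log_sd: float = 0.55
    shared_len_range: tuple[int, int] = (100, 1500)
    specific_te_count: int = 100  # per species
    specific_divergence_range: tuple[float, float] = (0.0, 0.05)
    tsd_len_range: tuple[int, int] = (2, 10)
    polya_fraction: float = 0.08  # LINE plants landing in a poly-A context
    erv: ErvSpec = field(default_factory=ErvSpec)
    n_stretch_count: int = 20
    composite_count: int = 1
    min_event_spacing: int = 300
    edge_margin: int = 2000

    def validate(self, check_events: bool = True) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("substitution_rate", "small_indel_rate", "gc", "polya_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ancestor_length <= 0:
            raise ValueError("ancestor_length must be positive")
        lo, hi = self.tsd_len_range
        if not (0 < lo <= hi):
            raise ValueError("tsd_len_range must be positive and ordered")
        if not check_events:
            return
        n_events = self.n_events_total()
        capacity = self.ancestor_length - 2 * self.edge_margin
        if n_events * self.min_event_spacing >= capacity:
            raise ValueError(
                "programmed events overlap: "
                f"{n_events} events x {self.min_event_spacing} nt spacing do not "
                f"fit in {capacity} nt"
            )

    def n_shared(self) -> int:
        return int(round(self.shared_te_density * self.ancestor_length / 1e6))

    def n_events_total(self) -> int:
        return (
            self.n_shared()
            + 2 * self.specific_te_count
            + self.n_stretch_count
            + (1 if self.erv.recombination else 0)
            + self.composite_count
        )


@dataclass
class TruthEvent:
    """One planted event with exact final coordinates in both genomes."""

    event_type: str  # shared | specific_A | specific_B | solo_ltr_recombination
    #                 | composite | n_artifact
    consensus_id: str
    superfamily: str
    tsd: str | None = None
    divergence: float = 0.0
    truncation_frac: float = 0.0
    a_interval: tuple[int, int] | None = None  # inserted block in genome A
    b_interval: tuple[int, int] | None = None
    a_element: tuple[int, int] | None = None  # element only (TSD excluded)
    b_element: tuple[int, int] | None = None
    a_pos: int | None = None  # orthologous (empty-site) point when no block
    b_pos: int | None = None
    components: list[str] | None = None  # composite members

    @property
    def carrier(self) -> str:
        if self.event_type == "specific_A":
            return "A"
        if self.event_type == "specific_B":
            return "B"
        if self.event_type in ("shared",):
            return "both"
        return {"solo_ltr_recombination": "B", "composite": "AB", "n_artifact": "AB"}.get(
            self.event_type, "?"
        )


@dataclass
class TruthManifest:
    seed: int
    length_a: int = 0
    length_b: int = 0
    events: list[TruthEvent] = field(default_factory=list)

    def of_type(self, *types: str) -> list[TruthEvent]:
        return [e for e in self.events if e.event_type in types]


_REQUIRED_EVENT_KEYS = {"event_type", "consensus_id", "superfamily"}


def write_truth(manifest: TruthManifest, path: str | Path) -> None:
    data = dict(
        seed=manifest.seed,
        length_a=manifest.length_a,
        length_b=manifest.length_b,
        events=[asdict(e) for e in manifest.events],
    )
    Path(path).write_text(json.dumps(data, indent=1))


def read_truth(path: str | Path) -> TruthManifest:
    data = json.loads(Path(path).read_text())
    manifest = TruthManifest(
        seed=data["seed"], length_a=data["length_a"], length_b=data["length_b"]
    )
    lengths = {"a": data["length_a"], "b": data["length_b"]}
    for i, raw in enumerate(data["events"]):
        missing = _REQUIRED_EVENT_KEYS - raw.keys()
        if missing:
            raise ValueError(f"event {i}: missing keys {sorted(missing)}")
        for key in ("a_interval", "b_interval", "a_element", "b_element"):
            iv = raw.get(key)
            if iv is not None:
                s, e = iv
                if not (0 <= s < e <= lengths[key[0]]):
                    raise ValueError(
                        f"event {i} ({raw['event_type']}): bad coordinate {key}={iv}"
                    )
                raw[key] = (s, e)
        manifest.events.append(TruthEvent(**raw))
    return manifest


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def simulate_ancestor(config: SimulationConfig, rng: np.random.Generator | None = None) -> str:
    """i.i.d. ancestral sequence at the configured GC content."""
    config.validate(check_events=False)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p_gc = config.gc / 2
    p_at = (1 - config.gc) / 2
    draws = rng.choice(4, size=config.ancestor_length, p=[p_at, p_gc, p_gc, p_at])
    return "".join(BASES[draws])


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    rng: np.random.Generator,
    indel_rate: float = 0.0,
    indel_mean_len: float = 3.0,
) -> tuple[str, int]:
    """Apply uniform substitutions (and optionally small indels) to a sequence.

    Returns (mutated sequence, number of substitutions applied).
    """
    n = len(seq)
    if n == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_sub = rng.binomial(n, substitution_rate)
    if n_sub:
        pos = rng.choice(n, size=n_sub, replace=False)
        for p in pos:
            cur = chr(arr[p])
            if cur not in "ACGT":
                continue
            alt = "ACGT".replace(cur, "")
            arr[p] = ord(alt[rng.integers(3)])
    out = arr.tobytes().decode()
    if indel_rate > 0 and n > 2:
        n_ind = rng.binomial(n, indel_rate)
        if n_ind:
            positions = sorted(rng.integers(1, n - 1, size=n_ind), reverse=True)
            chars = list(out)
            for p in positions:
                length = int(rng.geometric(1.0 / indel_mean_len))
                if rng.random() < 0.5:
                    del chars[p : p + length]
                else:
                    ins = "".join(BASES[rng.integers(0, 4, size=length)])
                    chars[p:p] = list(ins)
            out = "".join(chars)
    return out, int(n_sub)


def _other_base(base: str, avoid: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base and b != avoid]
    return choices[rng.integers(len(choices))]


def plant_insertion(
    seq: str,
    consensus: TEConsensus,
    pos: int,
    tsd_len: int,
    truncation_frac: float,
    divergence: float,
    rng: np.random.Generator,
) -> tuple[str, TruthEvent]:
    """Insert a (possibly 5'-truncated, point-mutated) consensus copy at pos.

    The element is framed by an exact duplication of the ``tsd_len`` target
    bases at ``pos``.  One guard base on each side of the element is adjusted
    when a chance extension would lengthen the apparent duplication, so the
    recorded TSD is exactly the maximal one.  Returns the edited sequence and
    the manifest entry (coordinates on the edited sequence).
    """
    if not 0 < pos < len(seq) - tsd_len:
        raise ValueError(f"position {pos} out of range")
    if not 0 <= truncation_frac < 1:
        raise ValueError("truncation_frac must be in [0, 1)")
    L = len(consensus.sequence)
    start = int(truncation_frac * L)
    element, n_sub = mutate_sequence(consensus.sequence[start:], divergence, rng)
    elem = list(element)
    tsd = seq[pos : pos + tsd_len]
    if tsd_len:
        if elem[-1] == seq[pos - 1]:
            elem[-1] = _other_base(elem[-1], seq[pos - 1], rng)
        if elem[0] == seq[pos + tsd_len]:
            elem[0] = _other_base(elem[0], seq[pos + tsd_len], rng)
    element = "".join(elem)
    new = seq[: pos + tsd_len] + element + tsd + seq[pos + tsd_len :]
    s = pos + tsd_len
    event = TruthEvent(
        event_type="specific_A",
        consensus_id=consensus.id,
        superfamily=consensus.superfamily,
        tsd=tsd if tsd_len else None,
        divergence=n_sub / max(len(element), 1),
        truncation_frac=truncation_frac,
        a_interval=(s, s + len(element) + tsd_len),
        a_element=(s, s + len(element)),
    )
    return new, event


# ---------------------------------------------------------------------------
# default library
# ---------------------------------------------------------------------------


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def default_library(erv: ErvSpec | None = None) -> list[TEConsensus]:
    """The synthetic consensus library used by the simulator.

    Consensus sequences are synthetic (random at fixed seed); ids and
    structure echo the superfamilies dominating the coelacanth TE landscape:
    CR1/L1/L2 LINEs, two tRNA-derived SINE families, a Gypsy LTR element, an
    ERV with two identical LTRs, and a MITE with terminal inverted repeats.
    """
    erv = erv or ErvSpec()
    rng = np.random.default_rng(_LIBRARY_SEED)
    lib = [
        TEConsensus("CR1-Coe", "CR1", _rand_seq(rng, 4500), is_autonomous=True),
        TEConsensus("L1-Coe", "L1", _rand_seq(rng, 4000), is_autonomous=True),
        TEConsensus("L2-Coe", "L2", _rand_seq(rng, 3400), is_autonomous=True),
        TEConsensus("CoeG-SINE", "SINE", _rand_seq(rng, 320)),
        TEConsensus("LF-SINE", "SINE", _rand_seq(rng, 260)),
        TEConsensus("Gypsy-Coe", "Gypsy", _rand_seq(rng, 4800), is_autonomous=True),
    ]
    ltr = _rand_seq(rng, erv.ltr_length)
    core = _rand_seq(rng, erv.core_length)
    lib.append(
        TEConsensus(
            "CoeERV1",
            "ERV",
            ltr + core + ltr,
            is_autonomous=True,
            declared_ltr_length=erv.ltr_length,
        )
    )
    tir = _rand_seq(rng, 25)
    lib.append(TEConsensus("MITE-Coe", "MITE", tir + _rand_seq(rng, 180) + revcomp(tir)))
    return lib


_SPECIFIC_MIX = {
    "CR1-Coe": 0.62, "L1-Coe": 0.08, "L2-Coe": 0.04, "CoeG-SINE": 0.08,
    "LF-SINE": 0.07, "Gypsy-Coe": 0.04, "MITE-Coe": 0.07,
}
_SHARED_MIX = {
    "CR1-Coe": 0.25, "CoeG-SINE": 0.18, "LF-SINE": 0.30, "L1-Coe": 0.05,
    "L2-Coe": 0.04, "Gypsy-Coe": 0.05, "CoeERV1": 0.05, "MITE-Coe": 0.08,
}
_SHORT_FAMILIES = {"CoeG-SINE", "LF-SINE", "MITE-Coe"}
_LINE_FAMILIES = {"CR1-Coe", "L1-Coe", "L2-Coe"}


import functools


@functools.lru_cache(maxsize=1)
def _specific_length_params() -> tuple[float, float]:
    """Log-normal parameters fitted to the 27 reference insertion lengths."""
    from .summarize import load_reference_insertion_table

    lengths = load_reference_insertion_table()["length_nt"].to_numpy(dtype=float)
    logs = np.log(lengths)
    return float(logs.mean()), float(logs.std())


# ---------------------------------------------------------------------------
# the pair simulator
# ---------------------------------------------------------------------------


@dataclass
class _Segment:
    text_a: str | None  # None => absent in that species
    text_b: str | None
    kind: str  # flank | event | slot
    event: TruthEvent | None = None
    tsd_len: int = 0


@dataclass
class SimResult:
    genome_a: str
    genome_b: str
    library: list[TEConsensus]
    manifest: TruthManifest
    config: SimulationConfig


class PairSimulator:
    """Stages: plan events -> build ancestor segments -> speciate -> plant."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.library = default_library(config.erv)
        self.by_id = {c.id: c for c in self.library}

    # -- planning -----------------------------------------------------------

    def _positions(self, n: int) -> list[int]:
        cfg = self.config
        lo, hi = cfg.edge_margin, cfg.ancestor_length - cfg.edge_margin
        chosen: list[int] = []
        tries = 0
        import bisect

        while len(chosen) < n:
            tries += 1
            if tries > 200 * n + 1000:
                raise ValueError("could not place events without overlap")
            p = int(self.rng.integers(lo, hi))
            i = bisect.bisect_left(chosen, p)
            if i > 0 and p - chosen[i - 1] < cfg.min_event_spacing:
                continue
            if i < len(chosen) and chosen[i] - p < cfg.min_event_spacing:
                continue
            chosen.insert(i, p)
        return chosen

    def _draw_tsd_len(self) -> int:
        lo, hi = self.config.tsd_len_range
        return int(self.rng.integers(lo, hi + 1))

    def _draw_element(self, mix: dict[str, float], length_draw, div_range):
        ids = list(mix)
        probs = np.array([mix[i] for i in ids])
        probs = probs / probs.sum()
        cid = ids[self.rng.choice(len(ids), p=probs)]
        cons = self.by_id[cid]
        L = len(cons.sequence)
        if cid in _SHORT_FAMILIES:
            start = 0
        else:
            target = int(np.clip(length_draw(), 150, L))
            start = L - target
        div = float(self.rng.uniform(*div_range))
        element, n_sub = mutate_sequence(cons.sequence[start:], div, self.rng)
        return cons, element, start / L, n_sub / max(len(element), 1)

    # -- stage 1: ancestor with shared plants -------------------------------

    def build(self) -> SimResult:
        cfg = self.config
        ancestor = simulate_ancestor(cfg, self.rng)
        n_shared = cfg.n_shared()
        labels = (
            ["shared"] * n_shared
            + ["specific_A"] * cfg.specific_te_count
            + ["specific_B"] * cfg.specific_te_count
            + ["n_artifact"] * cfg.n_stretch_count
            + (["erv"] if cfg.erv.recombination else [])
            + ["composite"] * cfg.composite_count
        )
        positions = self._positions(len(labels))
        order = self.rng.permutation(len(labels))
        planned = sorted(zip(positions, [labels[i] for i in order]))

        mu, sigma = _specific_length_params()
        spec_len = lambda: float(self.rng.lognormal(mu, sigma))
        shared_len = lambda: float(
            np.clip(
                self.rng.lognormal(cfg.shared_len_log_mean, cfg.shared_len_log_sd),
                *cfg.shared_len_range,
            )
        )

        master: list[_Segment] = []
        cur = 0
        for pos, label in planned:
            if label == "shared":
                t = self._draw_tsd_len()
                tsd = ancestor[pos : pos + t]
                master.append(_Segment(ancestor[cur : pos + t], None, "flank"))
                cons, element, trunc, div = self._draw_element(
                    _SHARED_MIX,
                    lambda: np.clip(shared_len(), 100, None),
                    cfg.shared_divergence_range,
                )
                ev = TruthEvent(
                    event_type="shared",
                    consensus_id=cons.id,
                    superfamily=cons.superfamily,
                    tsd=tsd,
                    divergence=div,
                    truncation_frac=trunc,
                )
                master.append(_Segment(element + tsd, None, "event", ev, t))
                cur = pos + t
            else:
                master.append(_Segment(ancestor[cur:pos], None, "flank"))
                ev = TruthEvent(event_type=label, consensus_id="", superfamily="")
                master.append(_Segment(None, None, "slot", ev))
                cur = pos
        master.append(_Segment(ancestor[cur:], None, "flank"))

        # -- stage 2: speciation -------------------------------------------
        sub = cfg.substitution_rate / 2
        ind = cfg.small_indel_rate / 2
        for seg in master:
            if seg.kind == "flank":
                seg.text_b, _ = mutate_sequence(
                    seg.text_a, sub, self.rng, ind, cfg.indel_mean_len
                )
                seg.text_a, _ = mutate_sequence(
                    seg.text_a, sub, self.rng, ind, cfg.indel_mean_len
                )
            elif seg.kind == "event":
                seg.text_b, _ = mutate_sequence(seg.text_a, sub, self.rng)
                seg.text_a, _ = mutate_sequence(seg.text_a, sub, self.rng)

        # -- stage 3: species-specific planting ----------------------------
        for i, seg in enumerate(master):
            if seg.kind != "slot":
                continue
            prev_seg, next_seg = master[i - 1], master[i + 1]
            label = seg.event.event_type
            if label in ("specific_A", "specific_B"):
                self._plant_specific(seg, prev_seg, next_seg, label[-1])
            elif label == "n_artifact":
                self._plant_artifact(seg, prev_seg, next_seg)
            elif label == "erv":
                self._plant_erv(seg, prev_seg, next_seg)
            elif label == "composite":
                self._plant_composite(seg, prev_seg, next_seg)

        # -- stage 4: assembly and coordinates -----------------------------
        manifest = TruthManifest(seed=cfg.seed)
        genome_a = self._assemble(master, "a", manifest)
        genome_b = self._assemble(master, "b", manifest)
        manifest.length_a = len(genome_a)
        manifest.length_b = len(genome_b)
        events = [seg.event for seg in master if seg.event is not None]
        manifest.events = sorted(
            events, key=lambda e: (e.a_interval or (e.a_pos or 0, 0))[0]
        )
        self._check(genome_a, genome_b, master)
        return SimResult(genome_a, genome_b, self.library, manifest, cfg)

    # -- planting helpers ---------------------------------------------------

    def _guarded(self, element: str, prev_text: str, next_text: str, t: int) -> str:
        """Adjust element edge bases so the planted TSD is the maximal duplication."""
        elem = list(element)
        if t and prev_text and elem[-1] == prev_text[-1]:
            elem[-1] = _other_base(elem[-1], prev_text[-1], self.rng)
        if t and len(next_text) > t and elem[0] == next_text[t]:
            elem[0] = _other_base(elem[0], next_text[t], self.rng)
        return "".join(elem)

    def _plant_specific(self, seg, prev_seg, next_seg, species: str) -> None:
        cfg = self.config
        mu, sigma = _specific_length_params()
        cons, element, trunc, div = self._draw_element(
            _SPECIFIC_MIX,
            lambda: float(np.clip(self.rng.lognormal(mu, sigma), 225, 5091)),
            cfg.specific_divergence_range,
        )
        ev = seg.event
        ev.consensus_id = cons.id
        ev.superfamily = cons.superfamily
        ev.truncation_frac = trunc
        ev.divergence = div
        polya = cons.id in _LINE_FAMILIES and self.rng.random() < cfg.polya_fraction
        prev = prev_seg.text_a if species == "A" else prev_seg.text_b
        nxt = next_seg.text_a if species == "A" else next_seg.text_b
        if polya:
            # the copy lands in a poly-A context: the target site is an A-run
            # shared by both species, and the element keeps a short A tail
            run = "A" * 20
            next_seg.text_a = run + next_seg.text_a[20:]
            next_seg.text_b = run + next_seg.text_b[20:]
            block = element + "A" * 8
            ev.tsd = None
            t = 0
        else:
            t = self._draw_tsd_len()
            tsd = nxt[:t]
            element = self._guarded(element, prev, nxt, t)
            block = tsd + element
            ev.tsd = tsd
        seg.tsd_len = t
        if species == "A":
            seg.text_a = block
        else:
            seg.text_b = block

    def _plant_artifact(self, seg, prev_seg, next_seg) -> None:
        """A TE insertion in one species mirrored by an equal-length N run."""
        cfg = self.config
        carrier = "A" if self.rng.random() < 0.5 else "B"
        cons, element, trunc, div = self._draw_element(
            _SPECIFIC_MIX,
            lambda: float(np.clip(self.rng.lognormal(*_specific_length_params()), 225, 5091)),
            cfg.specific_divergence_range,
        )
        t = self._draw_tsd_len()
        ev = seg.event
        ev.consensus_id = cons.id
        ev.superfamily = cons.superfamily
        ev.truncation_frac = trunc
        ev.divergence = div
        prev = prev_seg.text_a if carrier == "A" else prev_seg.text_b
        nxt = next_seg.text_a if carrier == "A" else next_seg.text_b
        tsd = nxt[:t]
        element = self._guarded(element, prev, nxt, t)
        ev.tsd = tsd
        seg.tsd_len = t
        block = tsd + element
        nblock = "N" * len(block)
        if carrier == "A":
            seg.text_a, seg.text_b = block, nblock
        else:
            seg.text_a, seg.text_b = nblock, block

    def _plant_erv(self, seg, prev_seg, next_seg) -> None:
        """Full two-LTR ERV in B; programmed solo LTR at the A orthologous site."""
        cfg = self.config
        cons = self.by_id["CoeERV1"]
        ltr_len = cons.declared_ltr_length
        t = cfg.erv.tsd_length
        # force the target-site bases equal in both species so the TSD string
        # is shared by the element and the solo LTR
        tsd = next_seg.text_b[:t]
        next_seg.text_a = tsd + next_seg.text_a[t:]
        element_b, nb = mutate_sequence(cons.sequence, cfg.erv.element_divergence, self.rng)
        solo_a, _ = mutate_sequence(
            cons.sequence[:ltr_len], cfg.erv.element_divergence, self.rng
        )
        element_b = self._guarded(element_b, prev_seg.text_b, next_seg.text_b, t)
        solo_a = self._guarded(solo_a, prev_seg.text_a, next_seg.text_a, t)
        ev = seg.event
        ev.event_type = "solo_ltr_recombination"
        ev.consensus_id = cons.id
        ev.superfamily = cons.superfamily
        ev.tsd = tsd
        ev.divergence = nb / len(element_b)
        seg.tsd_len = t
        seg.text_a = tsd + solo_a
        seg.text_b = tsd + element_b

    def _plant_composite(self, seg, prev_seg, next_seg) -> None:
        cfg = self.config
        species = "A" if self.rng.random() < 0.5 else "B"
        parts = ["LF-SINE", "CoeG-SINE", "LF-SINE"]
        pieces = []
        for cid in parts:
            piece, _ = mutate_sequence(
                self.by_id[cid].sequence, 0.01, self.rng
            )
            pieces.append(piece)
        element = "".join(pieces)
        t = self._draw_tsd_len()
        prev = prev_seg.text_a if species == "A" else prev_seg.text_b
        nxt = next_seg.text_a if species == "A" else next_seg.text_b
        tsd = nxt[:t]
        element = self._guarded(element, prev, nxt, t)
        ev = seg.event
        ev.consensus_id = "+".join(parts)
        ev.superfamily = "SINE"
        ev.tsd = tsd
        ev.divergence = 0.01
        ev.components = parts
        ev.event_type = "composite"
        # remember which species carries it via interval assignment
        seg.tsd_len = t
        if species == "A":
            seg.text_a = tsd + element
        else:
            seg.text_b = tsd + element

    # -- assembly -----------------------------------------------------------

    def _assemble(self, master, species: str, manifest: TruthManifest) -> str:
        parts = []
        off = 0
        for seg in master:
            text = seg.text_a if species == "a" else seg.text_b
            ev = seg.event
            if ev is not None:
                if text:
                    iv = (off, off + len(text))
                    if species == "a":
                        ev.a_interval = iv
                    else:
                        ev.b_interval = iv
                    self._set_element(ev, species, iv, seg.tsd_len)
                else:
                    if species == "a":
                        ev.a_pos = off
                    else:
                        ev.b_pos = off
            if text:
                parts.append(text)
                off += len(text)
        return "".join(parts)

    @staticmethod
    def _set_element(ev: TruthEvent, species: str, iv: tuple[int, int], t: int) -> None:
        s, e = iv
        if ev.event_type == "shared":
            elem = (s, e - t)  # block = element + TSD copy
        else:
            elem = (s + t, e)  # block = TSD copy + element
        if species == "a":
            ev.a_element = elem
        else:
            ev.b_element = elem

    def _check(self, genome_a: str, genome_b: str, master) -> None:
        off_a = off_b = 0
        for seg in master:
            if seg.text_a:
                assert genome_a[off_a : off_a + len(seg.text_a)] == seg.text_a
                off_a += len(seg.text_a)
            if seg.text_b:
                assert genome_b[off_b : off_b + len(seg.text_b)] == seg.text_b
                off_b += len(seg.text_b)
        assert off_a == len(genome_a) and off_b == len(genome_b)


def simulate_pair(config: SimulationConfig) -> SimResult:
    """Generate a genome pair, its library, and the ground-truth manifest."""
    return PairSimulator(config).build()
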