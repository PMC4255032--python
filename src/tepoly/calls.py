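"""Calling species-specific TE insertions at filled-vs-empty orthologous sites.

Annotated insertions of the two genomes are listed "face to face" through the
orthologous fragments: insertions whose lifted spans overlap reciprocally in
the same superfamily are shared; the remainder are candidate species-specific
insertions.  Each candidate is verified by a global affine-gap alignment of
the filled site against the orthologous empty site — the insertion is the
single maximal gap block in the empty sequence — after screening the empty
window for assembly N-stretches whose length matches the candidate (draft
assembly gaps masquerade as insertions and are flagged as artifacts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from ._align import global_aligner
from .annotate import AnnotatedInsertion
from .features import classify_flanks, tsd_for_indel, tsd_for_span
from .orthomap import OrthologousFragment, lift_flanked

logger = logging.getLogger(__name__)

DEFAULT_MIN_RECIPROCAL_OVERLAP = 0.5
DEFAULT_FLANK = 500
DEFAULT_FLANK_ID_FLOOR = 0.90
DEFAULT_MIN_CALL_LEN = 100


@dataclass
class SharedInsertionPair:
    insertion_a: AnnotatedInsertion
    insertion_b: AnnotatedInsertion
    reciprocal_overlap: float


@dataclass
class InsertionCall:
    """A species-specific (or artifact/rejected) insertion call."""

    carrier_species: str  # 'A' or 'B'
    insertion: AnnotatedInsertion
    status: str  # specific, artifact, rejected, composite, solo_ltr_counterpart
    filled_interval: tuple[int, int] | None = None
    empty_site_pos: int | None = None
    empty_window: tuple[int, int] | None = None  # window on the other species
    refined: bool = False
    tsd: str | None = None
    tsd_class: str = "not_detected"
    artifact_interval: tuple[int, int] | None = None
    note: str = ""
    ltr_pair: object | None = None
    solo_ltr_event: object | None = None
    composite: object | None = None
    copy_number_total: int | None = None
    copy_number_high: int | None = None
    transcriptome_hits: int | None = None

    @property
    def length(self) -> int:
        if self.filled_interval:
            return self.filled_interval[1] - self.filled_interval[0]
        return self.insertion.end - self.insertion.start


@dataclass
class CallSet:
    shared: list[SharedInsertionPair] = field(default_factory=list)
    calls: list[InsertionCall] = field(default_factory=list)
    excluded_a: list[AnnotatedInsertion] = field(default_factory=list)
    excluded_b: list[AnnotatedInsertion] = field(default_factory=list)

    def specific(self, species: str | None = None) -> list[InsertionCall]:
        out = [
            c
            for c in self.calls
            if c.status in ("specific", "composite", "solo_ltr_counterpart")
        ]
        if species:
            out = [c for c in out if c.carrier_species == species]
        return out

    def with_status(self, status: str) -> list[InsertionCall]:
        return [c for c in self.calls if c.status == status]

    def accounting(self) -> dict[str, int]:
        counts = dict(
            shared_pairs=len(self.shared),
            specific_A=len(self.specific("A")),
            specific_B=len(self.specific("B")),
            artifact=len(self.with_status("artifact")),
            rejected=len(self.with_status("rejected")),
            excluded=len(self.excluded_a) + len(self.excluded_b),
        )
        counts["total_annotations"] = (
            2 * counts["shared_pairs"]
            + counts["specific_A"]
            + counts["specific_B"]
            + counts["artifact"]
            + counts["rejected"]
            + counts["excluded"]
        )
        return counts


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def _fragment_for(trees: dict[str, IntervalTree], seq_id: str, start: int, end: int):
    tree = trees.get(seq_id)
    if tree is None:
        return None
    hits = tree.overlap(start, max(end, start + 1))
    best = None
    for iv in hits:
        if iv.begin <= start and end <= iv.end:
            if best is None or (iv.end - iv.begin) > (best.end - best.begin):
                best = iv
    return best.data if best else None


def _build_trees(fragments: list[OrthologousFragment]):
    at: dict[str, IntervalTree] = {}
    bt: dict[str, IntervalTree] = {}
    for f in fragments:
        at.setdefault(f.a_seq_id, IntervalTree()).addi(*f.a_interval, f)
        bt.setdefault(f.b_seq_id, IntervalTree()).addi(*f.b_interval, f)
    return at, bt


def pair_annotations(
    annots_a: list[AnnotatedInsertion],
    annots_b: list[AnnotatedInsertion],
    fragments: list[OrthologousFragment],
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
) -> tuple[
    list[SharedInsertionPair],
    list[AnnotatedInsertion],
    list[AnnotatedInsertion],
    list[AnnotatedInsertion],
    list[AnnotatedInsertion],
]:
    """Match annotations across species through the fragments, 1-to-1 greedy.

    Returns (shared, unpaired_a, unpaired_b, excluded_a, excluded_b) where
    excluded are annotations outside any orthologous fragment.
    """
    at, _ = _build_trees(fragments)
    b_trees: dict[str, IntervalTree] = {}
    for j, ins in enumerate(annots_b):
        b_trees.setdefault(ins.seq_id, IntervalTree()).addi(ins.start, ins.end, j)

    in_frag_a, excluded_a = [], []
    for ins in annots_a:
        frag = _fragment_for(at, ins.seq_id, ins.start, ins.end)
        if frag is None:
            logger.warning(
                "annotation %s:%d-%d outside orthologous fragments; excluded",
                ins.seq_id, ins.start, ins.end,
            )
            excluded_a.append(ins)
        else:
            in_frag_a.append((ins, frag))
    covered_b: set[int] = set()
    candidates = []  # (overlap_frac, i_a, j_b)
    for i, (ins, frag) in enumerate(in_frag_a):
        bl, br = lift_flanked(frag, ins.start, ins.end)
        tree = b_trees.get(frag.b_seq_id)
        if tree is None:
            continue
        for iv in tree.overlap(bl, max(br, bl + 1)):
            j = iv.data
            other = annots_b[j]
            if other.superfamily != ins.superfamily:
                continue
            ov = min(br, other.end) - max(bl, other.start)
            if ov <= 0:
                continue
            rec = min(
                ov / max(br - bl, 1),
                ov / max(other.end - other.start, 1),
            )
            if rec >= min_reciprocal_overlap:
                candidates.append((rec, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    shared: list[SharedInsertionPair] = []
    used_a: set[int] = set()
    for rec, i, j in candidates:
        if i in used_a or j in covered_b:
            continue
        used_a.add(i)
        covered_b.add(j)
        shared.append(SharedInsertionPair(in_frag_a[i][0], annots_b[j], rec))
    unpaired_a = [ins for i, (ins, _) in enumerate(in_frag_a) if i not in used_a]
    # b side: exclusion check against fragments' b intervals
    _, bt = _build_trees(fragments)
    unpaired_b, excluded_b = [], []
    for j, ins in enumerate(annots_b):
        if j in covered_b:
            continue
        if _fragment_for(bt, ins.seq_id, ins.start, ins.end) is None:
            logger.warning(
                "annotation %s:%d-%d outside orthologous fragments; excluded",
                ins.seq_id, ins.start, ins.end,
            )
            excluded_b.append(ins)
        else:
            unpaired_b.append(ins)
    return shared, unpaired_a, unpaired_b, excluded_a, excluded_b


# ---------------------------------------------------------------------------
# boundary refinement and artifact screening
# ---------------------------------------------------------------------------


@dataclass
class RefineResult:
    interval: tuple[int, int]  # on the filled window, 0-based half-open
    flank_identity_left: float
    flank_identity_right: float
    refined: bool


def refine_boundaries(
    filled_window: str,
    empty_window: str,
    flank: int = DEFAULT_FLANK,
    min_len: int = DEFAULT_MIN_CALL_LEN,
    flank_id_floor: float = DEFAULT_FLANK_ID_FLOOR,
) -> RefineResult | None:
    """Locate the insertion as the maximal gap block of the empty sequence.

    Global affine-gap alignment of the filled window against the empty
    window; the largest block where the filled sequence advances while the
    empty one does not is the insertion.  Returns None when no such block
    reaches ``min_len`` (the candidate is not an insertion).  Flanking
    alignment identity below ``flank_id_floor`` on either side leaves the
    call flagged unrefined.
    """
    if not filled_window or not empty_window:
        return None
    aln = global_aligner().align(filled_window, empty_window)[0]
    blocks = aln.aligned  # ((f_start,f_end),(e_start,e_end)) pairs
    if len(blocks[0]) == 0:
        return None
    fb, eb = blocks
    best = None  # (gap_len, f_start, f_end)
    for i in range(len(fb) - 1):
        df = int(fb[i + 1][0] - fb[i][1])
        de = int(eb[i + 1][0] - eb[i][1])
        gap = df - de
        if gap >= min_len and (best is None or gap > best[0]):
            best = (gap, int(fb[i][1]) + de, int(fb[i + 1][0]))
            # when both advance (de>0), attribute the shared part to flank
    if best is None:
        return None
    gap, fs, fe = best
    # flank identity on each side of the block, up to `flank` aligned columns
    def _side_identity(limit_lo: int, limit_hi: int) -> float:
        m = t = 0
        for (f0, f1), (e0, e1) in zip(fb, eb):
            lo = max(int(f0), limit_lo)
            hi = min(int(f1), limit_hi)
            if hi <= lo:
                continue
            off = int(e0) - int(f0)
            for x in range(lo, hi):
                t += 1
                if filled_window[x] == empty_window[x + off]:
                    m += 1
        return m / t if t else 0.0

    left_id = _side_identity(max(0, fs - flank), fs)
    right_id = _side_identity(fe, fe + flank)
    refined = left_id >= flank_id_floor and right_id >= flank_id_floor
    return RefineResult((fs, fe), left_id, right_id, refined)


def is_assembly_artifact(
    empty_window: str,
    insertion_len: int,
    n_frac: float = 0.9,
    len_tol: float = 0.1,
) -> tuple[bool, tuple[int, int] | None]:
    """Does the empty window contain an N-stretch matching the insertion length?

    Draft-assembly gap runs whose length matches the candidate insertion
    almost exactly indicate that the "insertion" is an artifact of the
    assembly, not a transposition event.
    """
    from ._align import find_n_runs

    for s, e, frac in find_n_runs(empty_window):
        if frac >= n_frac and abs((e - s) - insertion_len) <= len_tol * insertion_len:
            return True, (s, e)
    return False, None


def count_shared(shared_pairs: list[SharedInsertionPair]) -> dict[str, int]:
    """Per-superfamily counts of shared insertions (counted on species A)."""
    table: dict[str, int] = {}
    for p in shared_pairs:
        table[p.insertion_a.superfamily] = table.get(p.insertion_a.superfamily, 0) + 1
    table["total"] = len(shared_pairs)
    return table


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def call_insertions(
    annots_a: list[AnnotatedInsertion],
    annots_b: list[AnnotatedInsertion],
    fragments: list[OrthologousFragment],
    genomes_a: dict[str, str],
    genomes_b: dict[str, str],
    *,
    min_reciprocal_overlap: float = DEFAULT_MIN_RECIPROCAL_OVERLAP,
    flank: int = DEFAULT_FLANK,
    flank_id_floor: float = DEFAULT_FLANK_ID_FLOOR,
    min_call_len: int = DEFAULT_MIN_CALL_LEN,
) -> CallSet:
    """Full calling stage: pair, screen artifacts, refine, characterize TSDs."""
    from .orthomap import flip_fragment

    shared, unp_a, unp_b, exc_a, exc_b = pair_annotations(
        annots_a, annots_b, fragments, min_reciprocal_overlap
    )
    at, bt = _build_trees(fragments)
    callset = CallSet(shared=shared, excluded_a=exc_a, excluded_b=exc_b)

    def process(ins: AnnotatedInsertion, species: str) -> InsertionCall:
        if species == "A":
            frag = _fragment_for(at, ins.seq_id, ins.start, ins.end)
            carrier = genomes_a[ins.seq_id]
            other = genomes_b[frag.b_seq_id]
            bl, br = lift_flanked(frag, ins.start, ins.end)
        else:
            frag0 = _fragment_for(bt, ins.seq_id, ins.start, ins.end)
            frag = flip_fragment(frag0)
            carrier = genomes_b[ins.seq_id]
            other = genomes_a[frag.b_seq_id]
            bl, br = lift_flanked(frag, ins.start, ins.end)
        call = InsertionCall(carrier_species=species, insertion=ins, status="specific")
        span_len = ins.end - ins.start
        ws = max(0, bl - flank)
        we = min(len(other), br + flank)
        empty_window = other[ws:we]
        call.empty_window = (ws, we)
        call.empty_site_pos = (bl + br) // 2
        artifact, n_iv = is_assembly_artifact(empty_window, span_len)
        if artifact:
            call.status = "artifact"
            call.artifact_interval = (n_iv[0] + ws, n_iv[1] + ws)
            call.filled_interval = (ins.start, ins.end)
            return call
        fs = max(0, ins.start - flank)
        fe = min(len(carrier), ins.end + flank)
        filled_window = carrier[fs:fe]
        res = refine_boundaries(
            filled_window,
            empty_window,
            flank=flank,
            min_len=min_call_len,
            flank_id_floor=flank_id_floor,
        )
        if res is None:
            call.status = "rejected"
            call.note = "no insertion gap block in empty-site alignment"
            call.filled_interval = (ins.start, ins.end)
            return call
        s, e = res.interval
        call.filled_interval = (fs + s, fs + e)
        call.refined = res.refined
        tsd, tsd_class, elem_iv = tsd_for_indel(carrier, fs + s, fs + e)
        if tsd is None and tsd_class == "not_detected":
            # the aligner may have slid the gap by a base or two when a
            # lineage substitution sits right at the insertion edge; retry
            # anchored on the annotation boundaries with the indel length
            # fixing the duplication length
            expected = (fs + e) - (fs + s) - (ins.end - ins.start)
            tsd, tsd_class = tsd_for_span(
                carrier,
                ins.start,
                ins.end,
                slack=2,
                expected_len=expected if 2 <= expected <= 25 else None,
            )
        call.tsd = tsd
        call.tsd_class = tsd_class
        return call

    raw_calls = [process(ins, "A") for ins in unp_a] + [
        process(ins, "B") for ins in unp_b
    ]
    # de-duplicate near-identical specific calls on one carrier (two library
    # consensi can annotate the same locus); keep the higher-scoring one
    raw_calls.sort(
        key=lambda c: (c.carrier_species, c.insertion.seq_id, -c.insertion.score)
    )
    kept: list[InsertionCall] = []
    for c in raw_calls:
        if c.status == "specific" and c.filled_interval:
            dup = False
            for k in kept:
                if (
                    k.status == "specific"
                    and k.carrier_species == c.carrier_species
                    and k.insertion.seq_id == c.insertion.seq_id
                    and k.filled_interval
                ):
                    ov = min(k.filled_interval[1], c.filled_interval[1]) - max(
                        k.filled_interval[0], c.filled_interval[0]
                    )
                    if ov > 0.8 * min(c.length, k.length):
                        dup = True
                        break
            if dup:
                c.status = "rejected"
                c.note = "duplicate of an overlapping call"
        kept.append(c)
    kept.sort(key=lambda c: (c.carrier_species, c.insertion.seq_id, c.insertion.start))
    callset.calls = kept
    return callset


# ---------------------------------------------------------------------------
# text outputs
# ---------------------------------------------------------------------------


def calls_to_bed(calls: list[InsertionCall]) -> str:
    """BED6 (0-based half-open, native BED convention)."""
    lines = []
    for c in calls:
        if not c.filled_interval:
            continue
        s, e = c.filled_interval
        lines.append(
            "\t".join(
                [
                    c.insertion.seq_id,
                    str(s),
                    str(e),
                    f"{c.status}_{c.insertion.element_id}",
                    str(int(1000 * c.insertion.divergence)),
                    c.insertion.strand,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def calls_to_json(calls: list[InsertionCall]) -> list[dict]:
    out = []
    for c in calls:
        out.append(
            dict(
                carrier_species=c.carrier_species,
                seq_id=c.insertion.seq_id,
                element_id=c.insertion.element_id,
                superfamily=c.insertion.superfamily,
                consensus_id=c.insertion.consensus_id,
                status=c.status,
                span=[c.insertion.start, c.insertion.end],
                filled_interval=list(c.filled_interval) if c.filled_interval else None,
                length=c.length,
                empty_site_pos=c.empty_site_pos,
                refined=c.refined,
                tsd=c.tsd,
                tsd_class=c.tsd_class,
                divergence=round(c.insertion.divergence, 4),
                note=c.note,
            )
        )
    return out
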