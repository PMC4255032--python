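"""Annotation of TE copies in genomic sequence against a consensus library.

The annotator is a BLASTN-like seed-and-extend scheme: exact k-mer anchors
between genome and library (both strands), banded affine x-drop extension of
anchor clusters, identity computed from a full affine-gap alignment of the
final hit, then the census filters (length >= 100 nt, divergence to the
consensus <= 20%), and finally the joining of close hits that match
contiguous parts of the same consensus into a single insertion record, so a
copy fragmented by the local aligner is counted once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._align import affine_global_identity, encode, kmer_values, revcomp, xdrop_extend
from .library import ComplexityMask, TEConsensus, mask_low_complexity

logger = logging.getLogger(__name__)

DEFAULT_K = 12
DEFAULT_MIN_LEN = 100
DEFAULT_MAX_DIV = 0.20
DEFAULT_MAX_GENOME_GAP = 5000
DEFAULT_MAX_CONSENSUS_OVERLAP = 50


@dataclass
class RepeatHit:
    """A local alignment of a genomic interval against a library consensus."""

    seq_id: str
    start: int  # genome, 0-based half-open
    end: int
    strand: str  # '+' or '-'
    consensus_id: str
    cstart: int  # consensus, forward coordinates, 0-based half-open
    cend: int
    identity: float
    score: float

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedInsertion:
    """Merged hits forming one TE insertion (one 'element number')."""

    element_id: int
    seq_id: str
    components: list[RepeatHit]
    superfamily: str = "Unknown"

    @property
    def start(self) -> int:
        return min(h.start for h in self.components)

    @property
    def end(self) -> int:
        return max(h.end for h in self.components)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end

    @property
    def strand(self) -> str:
        return self.components[0].strand

    @property
    def consensus_id(self) -> str:
        return self.components[0].consensus_id

    @property
    def total_length(self) -> int:
        return sum(h.length for h in self.components)

    @property
    def identity(self) -> float:
        tot = self.total_length
        return sum(h.identity * h.length for h in self.components) / tot if tot else 0.0

    @property
    def divergence(self) -> float:
        return 1.0 - self.identity

    @property
    def score(self) -> float:
        return sum(h.score for h in self.components)


@dataclass
class Anchor:
    """A seed match between genome and consensus (working-strand coords)."""

    gpos: int
    consensus_id: str
    cpos: int
    strand: str


def _library_index(library: list[TEConsensus], k: int):
    """k-mer -> list of (library row, cpos_working, strand); consensi coded per strand."""
    index: dict[int, list[tuple[int, int, int]]] = {}
    coded = []  # (consensus, strand, codes_working)
    for ci, cons in enumerate(library):
        for si, strand in enumerate("+-"):
            seq = cons.sequence if strand == "+" else revcomp(cons.sequence)
            codes = encode(seq)
            coded.append(codes)
            vals, valid = kmer_values(codes, k)
            for pos in np.nonzero(valid)[0]:
                index.setdefault(int(vals[pos]), []).append((2 * ci + si, int(pos), si))
    return index, coded


def seed_matches(
    seq: str,
    library: list[TEConsensus],
    k: int = DEFAULT_K,
    mask: ComplexityMask | None = None,
) -> list[Anchor]:
    """All exact k-mer anchors between ``seq`` and the library (both strands).

    Anchors whose genomic k-mer lies inside the low-complexity mask are
    dropped.  Consensus positions are on the working strand (the reverse
    complement of the consensus for '-' anchors).
    """
    if not 8 <= k <= 16:
        raise ValueError("k must be in [8, 16]")
    index, _ = _library_index(library, k)
    if not index:
        return []
    codes = encode(seq)
    vals, valid = kmer_values(codes, k)
    if mask is not None and mask.intervals:
        flags = mask.position_flags(len(seq))
        valid = valid & ~flags[: len(valid)]
    keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    keys.sort()
    hitpos = np.nonzero(valid & np.isin(vals, keys))[0]
    anchors: list[Anchor] = []
    for gp in hitpos:
        for entry, cpos, si in index[int(vals[gp])]:
            cons = library[entry // 2]
            anchors.append(Anchor(int(gp), cons.id, cpos, "+-"[si]))
    return anchors


def extend_hit(
    anchor: Anchor,
    seq: str,
    consensus: TEConsensus,
    *,
    k: int = DEFAULT_K,
    x_drop: int = 20,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_extend: int = -1,
    band: int = 30,
    seq_codes: np.ndarray | None = None,
    cons_codes: np.ndarray | None = None,
    seq_id: str = "seq",
) -> RepeatHit:
    """Banded x-drop extension of an anchor into a :class:`RepeatHit`.

    Identity/divergence are computed from a full affine-gap global alignment
    of the final genomic and consensus intervals, the same scoring convention
    as the extension itself.
    """
    g = encode(seq) if seq_codes is None else seq_codes
    work = consensus.sequence if anchor.strand == "+" else revcomp(consensus.sequence)
    c = encode(work) if cons_codes is None else cons_codes
    gp, cp = anchor.gpos, anchor.cpos
    kw = dict(
        band=band, match=match, mismatch=mismatch, gap_open=gap_open, gap_ext=gap_extend, xdrop=x_drop
    )
    rs, ri, rj = xdrop_extend(g[gp + k :], c[cp + k :], **kw)
    ls, li, lj = xdrop_extend(g[:gp][::-1], c[:cp][::-1], **kw)
    gs, ge = gp - li, gp + k + ri
    cs, ce = cp - lj, cp + k + rj
    gsub = seq[gs:ge]
    csub = work[cs:ce]
    ident = affine_global_identity(gsub, csub)
    score = float(k * match + rs + ls)
    if anchor.strand == "-":
        L = len(consensus.sequence)
        cs, ce = L - ce, L - cs
    return RepeatHit(
        seq_id=seq_id,
        start=gs,
        end=ge,
        strand=anchor.strand,
        consensus_id=consensus.id,
        cstart=cs,
        cend=ce,
        identity=ident,
        score=score,
    )


def filter_hits(
    hits: list[RepeatHit],
    min_len: int = DEFAULT_MIN_LEN,
    max_div: float = DEFAULT_MAX_DIV,
    mask: ComplexityMask | None = None,
) -> list[RepeatHit]:
    """Apply the census filters: length >= min_len, divergence <= max_div
    (both inclusive); hits fully inside the low-complexity mask are removed."""
    if min_len < 0 or max_div < 0:
        raise ValueError("thresholds must be >= 0")
    out = []
    for h in hits:
        if h.length < min_len or h.divergence > max_div + 1e-12:
            continue
        if mask is not None and mask.covers(h.start, h.end):
            continue
        out.append(h)
    return out


def hits_mergeable(
    a: RepeatHit,
    b: RepeatHit,
    max_genome_gap: int = DEFAULT_MAX_GENOME_GAP,
    max_consensus_overlap: int = DEFAULT_MAX_CONSENSUS_OVERLAP,
) -> bool:
    """Whether two hits (a before b on the genome) are parts of one insertion."""
    if a.start > b.start:
        a, b = b, a
    if a.consensus_id != b.consensus_id or a.strand != b.strand:
        return False
    gap = b.start - a.end
    if gap > max_genome_gap or gap < -max_consensus_overlap:
        return False
    if a.strand == "+":
        # consensus must advance: b continues 3' of a, small overlap allowed
        return b.cstart >= a.cstart and b.cend >= a.cend and a.cend - b.cstart <= max_consensus_overlap
    # '-': forward-consensus coordinates run backwards along the genome
    return b.cstart <= a.cstart and b.cend <= a.cend and b.cend - a.cstart <= max_consensus_overlap


def merge_split_hits(
    hits: list[RepeatHit],
    max_genome_gap: int = DEFAULT_MAX_GENOME_GAP,
    max_consensus_overlap: int = DEFAULT_MAX_CONSENSUS_OVERLAP,
    superfamily_of: dict[str, str] | None = None,
) -> list[AnnotatedInsertion]:
    """Transitively merge close hits matching contiguous parts of one consensus.

    Hits sharing consensus and strand, with genomic gap <= max_genome_gap and
    consensus coordinates advancing consistently, receive one element number;
    output is sorted by span start.
    """
    n = len(hits)
    order = sorted(range(n), key=lambda i: (hits[i].start, hits[i].end))
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for oi in range(n):
        i = order[oi]
        for oj in range(oi + 1, n):
            j = order[oj]
            if hits[j].start - hits[i].end > max_genome_gap:
                break
            if hits_mergeable(hits[i], hits[j], max_genome_gap, max_consensus_overlap):
                union(i, j)
    groups: dict[int, list[RepeatHit]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(hits[i])
    insertions = []
    for comp in groups.values():
        comp.sort(key=lambda h: h.start)
        ins = AnnotatedInsertion(element_id=0, seq_id=comp[0].seq_id, components=comp)
        if superfamily_of:
            ins.superfamily = superfamily_of.get(ins.consensus_id, "Unknown")
        insertions.append(ins)
    insertions.sort(key=lambda x: (x.seq_id, x.start, x.end))
    for eid, ins in enumerate(insertions, start=1):
        ins.element_id = eid
    return insertions


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def _cluster_anchors(
    gpos: np.ndarray, cpos: np.ndarray, max_gap: int = 300, max_drift: int = 40
) -> list[tuple[int, int]]:
    """Group same-diagonal-ish anchors; returns (gpos, cpos) representatives."""
    diag = gpos - cpos
    order = np.lexsort((gpos, diag))
    reps = []
    cur: list[int] = []
    for idx in order:
        if cur:
            last = cur[-1]
            if abs(int(diag[idx]) - int(diag[last])) <= max_drift and 0 <= int(
                gpos[idx]
            ) - int(gpos[last]) <= max_gap:
                cur.append(int(idx))
                continue
            mid = cur[len(cur) // 2]
            reps.append((int(gpos[mid]), int(cpos[mid])))
            cur = []
        cur.append(int(idx))
    if cur:
        mid = cur[len(cur) // 2]
        reps.append((int(gpos[mid]), int(cpos[mid])))
    return reps


def annotate_sequence(
    seq: str,
    library: list[TEConsensus],
    seq_id: str = "seq",
    *,
    k: int = DEFAULT_K,
    min_len: int = DEFAULT_MIN_LEN,
    max_div: float = DEFAULT_MAX_DIV,
    max_genome_gap: int = DEFAULT_MAX_GENOME_GAP,
    max_consensus_overlap: int = DEFAULT_MAX_CONSENSUS_OVERLAP,
    mask: ComplexityMask | None | bool = True,
    x_drop: int = 20,
) -> list[AnnotatedInsertion]:
    """Full annotation of one sequence: seeds, extensions, filters, merging."""
    if mask is True:
        mask = mask_low_complexity(seq, seq_id=seq_id)
    elif mask is False:
        mask = None
    g_codes = encode(seq)
    vals, valid = kmer_values(g_codes, k)
    if mask is not None and mask.intervals and len(valid):
        flags = mask.position_flags(len(seq))
        valid = valid & ~flags[: len(valid)]
    index, coded = _library_index(library, k)
    if not index or not len(vals):
        return []
    keys = np.fromiter(index.keys(), dtype=np.int64, count=len(index))
    keys.sort()
    hitpos = np.nonzero(valid & np.isin(vals, keys))[0]
    # bucket anchors per (consensus, strand)
    buckets: dict[int, tuple[list[int], list[int]]] = {}
    for gp in hitpos:
        for entry, cp, _si in index[int(vals[gp])]:
            b = buckets.setdefault(entry, ([], []))
            b[0].append(int(gp))
            b[1].append(cp)
    superfam = {c.id: c.superfamily for c in library}
    hits: list[RepeatHit] = []
    for entry, (gps, cps) in sorted(buckets.items()):
        cons = library[entry // 2]
        strand = "+-"[entry % 2]
        cons_codes = coded[entry]
        reps = _cluster_anchors(np.asarray(gps), np.asarray(cps))
        covered: list[tuple[int, int]] = []
        for gp, cp in reps:
            if any(s <= gp < e for s, e in covered):
                continue
            hit = extend_hit(
                Anchor(gp, cons.id, cp, strand),
                seq,
                cons,
                k=k,
                x_drop=x_drop,
                seq_codes=g_codes,
                cons_codes=cons_codes,
                seq_id=seq_id,
            )
            covered.append((hit.start, hit.end))
            hits.append(hit)
    hits = filter_hits(hits, min_len=min_len, max_div=max_div, mask=mask)
    return merge_split_hits(
        hits, max_genome_gap, max_consensus_overlap, superfamily_of=superfam
    )


# ---------------------------------------------------------------------------
# text outputs
# ---------------------------------------------------------------------------


def annotations_to_table(insertions: list[AnnotatedInsertion]):
    """RepeatMasker-like table (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for ins in insertions:
        for h in ins.components:
            rows.append(
                dict(
                    seq=ins.seq_id,
                    begin=h.start + 1,
                    end=h.end,
                    strand=h.strand,
                    repeat_id=h.consensus_id,
                    superfamily=ins.superfamily,
                    cons_begin=h.cstart + 1,
                    cons_end=h.cend,
                    pct_div=round(100 * h.divergence, 2),
                    element_id=ins.element_id,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "seq", "begin", "end", "strand", "repeat_id", "superfamily",
            "cons_begin", "cons_end", "pct_div", "element_id",
        ],
    )


def annotations_to_gff3(insertions: list[AnnotatedInsertion]) -> str:
    lines = ["##gff-version 3"]
    for ins in insertions:
        attrs = (
            f"ID=te{ins.element_id};element_id={ins.element_id};"
            f"superfamily={ins.superfamily};consensus={ins.consensus_id};"
            f"divergence={ins.divergence:.4f}"
        )
        lines.append(
            "\t".join(
                [
                    ins.seq_id, "tepoly", "dispersed_repeat",
                    str(ins.start + 1), str(ins.end), f"{ins.score:.0f}",
                    ins.strand, ".", attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def annotations_to_json(insertions: list[AnnotatedInsertion]) -> list[dict]:
    return [
        dict(
            element_id=ins.element_id,
            seq_id=ins.seq_id,
            superfamily=ins.superfamily,
            components=[
                [h.seq_id, h.start, h.end, h.strand, h.consensus_id, h.cstart,
                 h.cend, h.identity, h.score]
                for h in ins.components
            ],
        )
        for ins in insertions
    ]


def annotations_from_json(data: list[dict]) -> list[AnnotatedInsertion]:
    out = []
    for d in data:
        comps = [
            RepeatHit(
                seq_id=c[0], start=c[1], end=c[2], strand=c[3], consensus_id=c[4],
                cstart=c[5], cend=c[6], identity=c[7], score=c[8],
            )
            for c in d["components"]
        ]
        out.append(
            AnnotatedInsertion(
                element_id=d["element_id"],
                seq_id=d["seq_id"],
                components=comps,
                superfamily=d["superfamily"],
            )
        )
    return out
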