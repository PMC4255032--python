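"""Structural characterization of insertion calls.

Target-site duplications (TSDs) — the few nucleotides of host sequence
duplicated on both sides of an integration — are detected as the longest
exact string that is simultaneously a suffix of the left flank and a prefix
of the right flank of the element.  Long terminal repeats (LTRs) and
terminal inverted repeats (TIRs) are found by locally aligning the two ends
of an element against each other; a solo LTR at the orthologous site of a
two-LTR element, sharing the element's TSD, is the signature of homologous
recombination between the LTRs.  The module also provides composite-
insertion decomposition, copy-number and transcriptome-hit counting under
the classical family filters, and single-linkage subfamily clustering at
high nucleotide identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._align import (
    alignment_identity,
    global_identity,
    infix_best,
    local_aligner,
    revcomp,
)

logger = logging.getLogger(__name__)

TSD_MIN_LEN = 2
TSD_MAX_LEN = 25
POLYA_WINDOW = 20
POLYA_FRAC = 0.80
AT_RICH_WINDOW = 30
AT_RICH_FRAC = 0.85


@dataclass
class TSDResult:
    sequence: str
    length: int
    tsd_class: str  # TSD, polyA_region, AT_rich_region, not_detected


@dataclass
class LTRPair:
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    length: int
    identity: float
    kind: str = "LTR"  # LTR (direct) or TIR (inverted)


@dataclass
class SoloLTREvent:
    full_element_call: object  # InsertionCall of the two-LTR element
    solo_site_interval: tuple[int, int]  # on the other species
    ltr_identity_to_solo: float
    shared_tsd: str


@dataclass
class CompositeDecomposition:
    components: list[tuple[str, tuple[int, int], str, str | None]]
    coverage: float
    partial: bool


# ---------------------------------------------------------------------------
# TSD
# ---------------------------------------------------------------------------


def _frac(s: str, base: str) -> float:
    return s.count(base) / len(s) if s else 0.0


def classify_flanks(left_flank: str, right_flank: str) -> str:
    """Classify TSD-less flanks: poly-A, AT-rich, or nothing."""
    lw = left_flank[-POLYA_WINDOW:]
    rw = right_flank[:POLYA_WINDOW]
    for w in (lw, rw):
        if len(w) >= 10 and (_frac(w, "A") >= POLYA_FRAC or _frac(w, "T") >= POLYA_FRAC):
            return "polyA_region"
    lw = left_flank[-AT_RICH_WINDOW:]
    rw = right_flank[:AT_RICH_WINDOW]
    for w in (lw, rw):
        if len(w) >= 15 and _frac(w, "A") + _frac(w, "T") >= AT_RICH_FRAC:
            return "AT_rich_region"
    return "not_detected"


def find_tsd(
    left_flank: str,
    right_flank: str,
    min_len: int = TSD_MIN_LEN,
    max_len: int = TSD_MAX_LEN,
) -> TSDResult:
    """Longest exact duplication: suffix of the left flank = prefix of the right.

    Falls back to flank classification (poly-A / AT-rich) when no duplication
    of length in [min_len, max_len] exists.
    """
    if len(left_flank) < min_len or len(right_flank) < min_len:
        logger.warning("flank shorter than minimal TSD length; TSD not searched")
        return TSDResult("", 0, "not_detected")
    top = min(max_len, len(left_flank), len(right_flank))
    for t in range(top, min_len - 1, -1):
        if left_flank[-t:] == right_flank[:t]:
            return TSDResult(left_flank[-t:], t, "TSD")
    return TSDResult("", 0, classify_flanks(left_flank, right_flank))


def tsd_for_indel(
    genome: str,
    gap_start: int,
    gap_end: int,
    min_len: int = TSD_MIN_LEN,
    max_len: int = TSD_MAX_LEN,
) -> tuple[str | None, str, tuple[int, int]]:
    """TSD of an insertion located as an indel block [gap_start, gap_end).

    The aligner may place the gap anywhere within the target-site repeat, so
    the duplication is recovered from the two slide directions: t_r bases that
    precede the gap and also end it, plus t_l bases that start the gap and
    also follow it.  Returns (tsd or None, tsd_class, element_interval) with
    the element interval normalised to exclude the duplicated target site.
    Homopolymer A/T "duplications" are demoted to poly-A context.
    """
    s, e = gap_start, gap_end
    t_r = 0
    for t in range(1, min(max_len, s, e - s) + 1):
        if genome[s - t : s] == genome[e - t : e]:
            t_r = t
    t_l = 0
    for t in range(1, min(max_len, len(genome) - e, e - s) + 1):
        if genome[s : s + t] == genome[e : e + t]:
            t_l = t
    total = min(t_r + t_l, max_len)
    elem = (s + t_l, e - t_r) if t_r + t_l < (e - s) else (s, e)
    if total >= min_len:
        tsd = genome[s - t_r : s + t_l]
        tsd = tsd[:total]
        if len(tsd) >= 5 and (set(tsd) <= {"A"} or set(tsd) <= {"T"}):
            cls = classify_flanks(genome[max(0, elem[0] - 30) : elem[0]], genome[elem[1] : elem[1] + 30])
            return None, cls if cls != "not_detected" else "polyA_region", elem
        return tsd, "TSD", elem
    cls = classify_flanks(genome[max(0, s - 30) : s], genome[e : e + 30])
    return None, cls, elem


def tsd_for_span(
    genome: str,
    span_start: int,
    span_end: int,
    min_len: int = TSD_MIN_LEN,
    max_len: int = TSD_MAX_LEN,
    slack: int = 2,
    expected_len: int | None = None,
) -> tuple[str | None, str]:
    """TSD flanking an element whose boundaries are known only within ``slack``.

    Searches every boundary shift (ds, de) in [-slack, slack] for the longest
    duplication ending at the shifted start and beginning at the shifted end;
    among candidates prefers the longest, then the smallest shift.  With
    ``expected_len`` set (e.g. from an independent indel length), only
    duplications of exactly that length qualify, which suppresses chance
    micro-duplications.  Homopolymer A/T duplications are demoted to poly-A
    context, as in :func:`tsd_for_indel`.
    """
    best: tuple[int, int, str] | None = None  # (t, shift_cost, tsd)
    for ds in range(-slack, slack + 1):
        for de in range(-slack, slack + 1):
            s = span_start + ds
            e = span_end + de
            if not (0 < s < e <= len(genome)):
                continue
            top = min(max_len, s, len(genome) - e)
            t_found = 0
            for t in range(1, top + 1):
                if genome[s - t : s] == genome[e : e + t]:
                    t_found = t
            if t_found < min_len:
                continue
            if expected_len is not None and abs(t_found - expected_len) > 1:
                continue
            cand = (t_found, -(abs(ds) + abs(de)), genome[s - t_found : s])
            if best is None or cand[:2] > best[:2]:
                best = cand
    if best is None:
        return None, classify_flanks(
            genome[max(0, span_start - 30) : span_start], genome[span_end : span_end + 30]
        )
    tsd = best[2]
    if len(tsd) >= 5 and (set(tsd) <= {"A"} or set(tsd) <= {"T"}):
        return None, "polyA_region"
    return tsd, "TSD"


# ---------------------------------------------------------------------------
# LTR / TIR detection
# ---------------------------------------------------------------------------


def _terminal_repeat(
    element_seq: str, min_len: int, min_identity: float, end_slack: int, inverted: bool
) -> LTRPair | None:
    n = len(element_seq)
    if n < 2 * min_len:
        return None
    w = min(1500, n // 2)
    left = element_seq[:w]
    right = element_seq[n - w :]
    target = revcomp(right) if inverted else right
    aln = local_aligner().align(left, target)
    if len(aln) == 0:
        return None
    best = aln[0]
    blocks = best.aligned
    if len(blocks[0]) == 0:
        return None
    ls, le = int(blocks[0][0][0]), int(blocks[0][-1][1])
    rs, re = int(blocks[1][0][0]), int(blocks[1][-1][1])
    ident = alignment_identity(best)
    length = le - ls
    if length < min_len or ident < min_identity:
        return None
    if inverted:
        rs, re = w - re, w - rs
    r0 = n - w + rs
    r1 = n - w + re
    if ls > end_slack or (n - r1) > end_slack:
        return None
    return LTRPair(
        left_interval=(ls, le),
        right_interval=(r0, r1),
        length=length,
        identity=ident,
        kind="TIR" if inverted else "LTR",
    )


def detect_ltrs(
    element_seq: str,
    min_ltr: int = 100,
    min_identity: float = 0.80,
    end_slack: int = 50,
) -> LTRPair | None:
    """Direct terminal repeats (LTRs) by local alignment of the element ends."""
    return _terminal_repeat(element_seq, min_ltr, min_identity, end_slack, inverted=False)


def detect_tirs(
    element_seq: str,
    min_tir: int = 10,
    min_identity: float = 0.80,
    end_slack: int = 50,
) -> LTRPair | None:
    """Terminal inverted repeats (TIRs), the hallmark of MITEs/DNA transposons."""
    return _terminal_repeat(element_seq, min_tir, min_identity, end_slack, inverted=True)


def call_solo_ltr(
    call,
    ltr_pair: LTRPair,
    element_seq: str,
    empty_site_seq: str,
    empty_site_offset: int = 0,
    min_identity: float = 0.90,
    len_tol: float = 0.10,
    tsd_slack: int = 3,
) -> SoloLTREvent | None:
    """Solo-LTR recombination signature at the orthologous empty site.

    The empty site must align to one LTR of the filled element with identity
    >= ``min_identity`` and matched length within ``len_tol``, and both
    structures must be flanked by the same TSD string (searched within
    ``tsd_slack`` nt of the aligned solo boundaries to absorb alignment end
    wobble).
    """
    if ltr_pair is None or ltr_pair.kind != "LTR":
        return None
    ls, le = ltr_pair.left_interval
    ltr_seq = element_seq[ls:le]
    hit = infix_best(ltr_seq, empty_site_seq)
    if hit is None:
        return None
    ss, se, ident = hit
    if ident < min_identity:
        return None
    if abs((se - ss) - len(ltr_seq)) > len_tol * len(ltr_seq):
        return None
    tsd = getattr(call, "tsd", None)
    if not tsd:
        return None
    t = len(tsd)
    left_ok = any(
        0 <= ss + d - t and empty_site_seq[ss + d - t : ss + d] == tsd
        for d in range(-tsd_slack, tsd_slack + 1)
    )
    right_ok = any(
        empty_site_seq[se + d : se + d + t] == tsd
        for d in range(-tsd_slack, tsd_slack + 1)
        if se + d >= 0
    )
    if not (left_ok and right_ok):
        return None
    return SoloLTREvent(
        full_element_call=call,
        solo_site_interval=(ss + empty_site_offset, se + empty_site_offset),
        ltr_identity_to_solo=ident,
        shared_tsd=tsd,
    )


# ---------------------------------------------------------------------------
# composite decomposition
# ---------------------------------------------------------------------------


def decompose_composite(
    insertion_seq: str,
    library,
    min_component_len: int = 80,
    coverage_floor: float = 0.60,
    overlap_slack: int = 10,
) -> CompositeDecomposition:
    """Greedy highest-score tiling of library hits within one insertion."""
    from .annotate import annotate_sequence

    annots = annotate_sequence(
        insertion_seq, library, min_len=min_component_len, mask=False
    )
    annots.sort(key=lambda a: -a.score)
    chosen = []
    for a in annots:
        s, e = a.start, a.end
        if any(min(e, ce) - max(s, cs) > overlap_slack for _, (cs, ce), _, _ in chosen):
            continue
        left = insertion_seq[max(0, s - TSD_MAX_LEN) : s]
        right = insertion_seq[e : e + TSD_MAX_LEN]
        tsd = find_tsd(left, right) if left and right else TSDResult("", 0, "not_detected")
        chosen.append(
            (a.consensus_id, (s, e), a.strand, tsd.sequence if tsd.tsd_class == "TSD" else None)
        )
    chosen.sort(key=lambda c: c[1][0])
    covered = sum(e - s for _, (s, e), _, _ in chosen)
    coverage = covered / len(insertion_seq) if insertion_seq else 0.0
    return CompositeDecomposition(
        components=chosen, coverage=coverage, partial=coverage < coverage_floor
    )


# ---------------------------------------------------------------------------
# copy number / expression / clustering
# ---------------------------------------------------------------------------


def _query_hits(query: str, target: str, min_len: int, min_identity: float):
    """Merged seed-and-extend hits of ``query`` in ``target``."""
    from .annotate import annotate_sequence
    from .library import TEConsensus

    if len(query) < 50:
        return []
    cons = TEConsensus("query", "Unknown", query)
    annots = annotate_sequence(
        target,
        [cons],
        min_len=min_len,
        max_div=1.0 - min_identity,
        mask=False,
    )
    return annots


def copy_number(
    query: str,
    target_seqs: list[str],
    min_len_frac: float = 0.80,
    min_identity: float = 0.80,
    high_identity: float = 0.98,
) -> tuple[int, int]:
    """Copies of ``query`` in the target sequences under the family filters.

    A hit must cover >= ``min_len_frac`` of the query length at identity
    >= ``min_identity``; overlapping hits keep the best per locus.  The
    second count additionally requires identity >= ``high_identity``.
    """
    if len(query) < 100:
        raise ValueError("query must be >= 100 nt")
    min_len = int(round(min_len_frac * len(query)))
    n_total = n_high = 0
    for target in target_seqs:
        annots = _query_hits(query, target, min_len, min_identity)
        loci: list[tuple[int, int, float]] = []
        for a in sorted(annots, key=lambda x: -x.score):
            s, e = a.start, a.end
            if e - s < min_len or a.identity < min_identity:
                continue
            if any(min(e, le) - max(s, ls) > 0.5 * min(e - s, le - ls) for ls, le, _ in loci):
                continue
            loci.append((s, e, a.identity))
        n_total += len(loci)
        n_high += sum(1 for _, _, ident in loci if ident >= high_identity)
    return n_total, n_high


def expression_hits(
    query: str,
    transcripts: list[str],
    min_hit_len: int = 80,
    min_identity: float = 0.95,
) -> int:
    """Number of distinct transcripts with >= 1 qualifying local hit."""
    count = 0
    for tr in transcripts:
        annots = _query_hits(query, tr, min_hit_len, min_identity)
        if any(
            a.total_length >= min_hit_len and a.identity >= min_identity for a in annots
        ):
            count += 1
    return count


def cluster_subfamily(
    seqs: list[str], id_threshold: float = 0.98
) -> tuple[list[list[int]], "object"]:
    """Single-linkage clusters under pairwise global-alignment identity.

    Returns (clusters as lists of sequence indices, pairwise identity
    DataFrame).
    """
    import numpy as np
    import pandas as pd

    if not seqs:
        raise ValueError("at least one sequence required")
    n = len(seqs)
    mat = np.eye(n)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_identity(seqs[i], seqs[j])
            mat[i, j] = mat[j, i] = ident
            if ident >= id_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = sorted(groups.values(), key=lambda g: g[0])
    df = pd.DataFrame(np.round(mat, 4))
    return clusters, df
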