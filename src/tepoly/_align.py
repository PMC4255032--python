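"""Low-level sequence and alignment primitives shared across the pipeline.

Fast paths: numpy for k-mer scanning, a numba banded x-drop kernel for
seed extension, edlib for unit-cost full DP (identity, infix search) and
Bio.Align.PairwiseAligner for affine-gap global/local alignments.
"""

from __future__ import annotations

import functools

import edlib
import numpy as np
from Bio import Align
from numba import njit

NEG = -(10**9)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling k-mer integer values and a validity mask (False where any N).

    Returns arrays of length ``len(codes) - k + 1``.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    vals = np.zeros(n, dtype=np.int64)
    for j in range(k):
        vals += codes[j : j + n].astype(np.int64) << (2 * (k - 1 - j))
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(bad)])
    valid = (cs[k:] - cs[:-k]) == 0
    return vals, valid


# ---------------------------------------------------------------------------
# banded affine x-drop extension (numba)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _xdrop_kernel(g, c, band, match, mismatch, gap_open, gap_ext, xdrop):  # pragma: no cover
    """Extend an alignment of g vs c from their origins (cell (0,0) = score 0).

    Returns (best_score, best_i, best_j): number of bases of g and c consumed
    at the best-scoring cell under banded affine DP with x-drop pruning.
    """
    W = 2 * band + 1
    H_prev = np.full(W, NEG, dtype=np.int64)
    F_prev = np.full(W, NEG, dtype=np.int64)
    H_cur = np.full(W, NEG, dtype=np.int64)
    F_cur = np.full(W, NEG, dtype=np.int64)
    # row i = 0: horizontal gaps from origin
    H_prev[band] = 0
    for idx in range(band + 1, W):
        j = idx - band
        if j > c.size:
            break
        v = gap_open + (j - 1) * gap_ext
        if v >= -xdrop:
            H_prev[idx] = v
    best = 0
    best_i = 0
    best_j = 0
    ng = g.size
    nc = c.size
    for i in range(1, ng + 1):
        for idx in range(W):
            H_cur[idx] = NEG
            F_cur[idx] = NEG
        e = NEG
        row_alive = False
        for idx in range(W):
            j = idx - band + i
            if j < 0 or j > nc:
                continue
            # vertical (consume g only): from (i-1, j) at idx+1
            f = NEG
            if idx + 1 < W:
                a = H_prev[idx + 1] + gap_open
                b = F_prev[idx + 1] + gap_ext
                f = a if a > b else b
            F_cur[idx] = f
            h = f
            if h < e:
                h = e
            if j >= 1:
                # diagonal: from (i-1, j-1) at same idx
                gi = g[i - 1]
                cj = c[j - 1]
                if gi == cj and gi < 4:
                    s = match
                else:
                    s = mismatch
                m = H_prev[idx] + s
                if m > h:
                    h = m
            if h < best - xdrop:
                h = NEG
            H_cur[idx] = h
            if h > NEG:
                row_alive = True
                if h > best:
                    best = h
                    best_i = i
                    best_j = j
            # E for next cell in the row (consume c only)
            a = h + gap_open
            b = e + gap_ext
            e = a if a > b else b
        if not row_alive:
            break
        H_prev, H_cur = H_cur, H_prev
        F_prev, F_cur = F_cur, F_prev
    return best, best_i, best_j


def xdrop_extend(
    g_codes: np.ndarray,
    c_codes: np.ndarray,
    *,
    band: int = 30,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -5,
    gap_ext: int = -1,
    xdrop: int = 20,
) -> tuple[int, int, int]:
    """Banded affine x-drop extension aligning prefixes of two coded arrays."""
    return _xdrop_kernel(
        np.ascontiguousarray(g_codes),
        np.ascontiguousarray(c_codes),
        band,
        match,
        mismatch,
        gap_open,
        gap_ext,
        xdrop,
    )


# ---------------------------------------------------------------------------
# edlib wrappers
# ---------------------------------------------------------------------------


def _cigar_counts(cigar: str) -> tuple[int, int, int, int]:
    eq = x = ins = dele = 0
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            if ch == "=":
                eq += n
            elif ch == "X":
                x += n
            elif ch == "I":
                ins += n
            elif ch == "D":
                dele += n
            n = 0
    return eq, x, ins, dele


def global_identity(a: str, b: str) -> float:
    """Identity of the unit-cost global alignment: matches / aligned non-gap columns."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    eq, x, _, _ = _cigar_counts(res["cigar"])
    return eq / (eq + x) if eq + x else 0.0


def infix_best(query: str, text: str) -> tuple[int, int, float] | None:
    """Best match of ``query`` inside ``text`` (edlib HW): (start, end, identity)."""
    if not query or not text or len(query) > len(text) + 50:
        pass
    res = edlib.align(query, text, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    eq, x, _, _ = _cigar_counts(res["cigar"])
    ident = eq / (eq + x) if eq + x else 0.0
    return s, e + 1, ident


# ---------------------------------------------------------------------------
# Biopython affine aligners
# ---------------------------------------------------------------------------


@functools.lru_cache(maxsize=None)
def global_aligner(free_end_gaps: bool = False) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1.0
    al.mismatch_score = -2.0
    al.open_gap_score = -6.0
    al.extend_gap_score = -1.0
    if free_end_gaps:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    return al


@functools.lru_cache(maxsize=None)
def local_aligner(match: float = 2.0, mismatch: float = -3.0) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    return al


def alignment_identity(alignment) -> float:
    """matches / aligned non-gap columns of a Bio.Align alignment."""
    c = alignment.counts()
    aligned = c.identities + c.mismatches
    return c.identities / aligned if aligned else 0.0


def affine_global_identity(a: str, b: str) -> float:
    """Identity under an affine-gap global alignment (match 1, mismatch -2,
    gap -6/-1), the same convention as local-alignment scoring; unit-cost
    edit distance would convert mismatch runs into indel pairs and
    overestimate identity on divergent copies."""
    if not a or not b:
        return 0.0
    return alignment_identity(global_aligner().align(a, b)[0])


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def find_n_runs(seq: str, merge_gap: int = 10) -> list[tuple[int, int, float]]:
    """Maximal N-runs (merged across short non-N interruptions).

    Returns (start, end, n_fraction) per run.
    """
    import re

    raw = [(m.start(), m.end()) for m in re.finditer("N+", seq)]
    if not raw:
        return []
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        n = seq.count("N", s, e)
        out.append((s, e, n / (e - s)))
    return out
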