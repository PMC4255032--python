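"""Orthologous-fragment mapping between two genomes and coordinate liftover.

Orthology between the two sequence sets is established by a high-identity
anchor matcher (maximal exact matches extended ungapped while identity stays
above a floor) followed by colinear chaining of anchors into fragments, the
automated equivalent of picking the main alignment diagonals of a megablast
comparison.  Each fragment carries its anchor list and supports liftover of
positions from genome A to genome B (and back via :func:`flip_fragment`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from ._align import encode, kmer_values, revcomp

DEFAULT_SEED_LEN = 20
DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MAX_DIAG_DRIFT = 200
DEFAULT_MAX_GAP = 10_000
DEFAULT_MAX_OCC = 16


@dataclass
class Anchor:
    """An ungapped high-identity match; b coordinates on the forward strand."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def weight(self) -> float:
        return self.length * self.identity


@dataclass
class OrthologousFragment:
    """A chained, oriented correspondence between intervals of two genomes."""

    a_seq_id: str
    b_seq_id: str
    a_interval: tuple[int, int]
    b_interval: tuple[int, int]
    orientation: str
    anchors: list[Anchor]
    mean_identity: float
    score: float = 0.0  # summed anchor weight of this fragment
    chain_score: float = 0.0  # DP score of the chain the fragment came from
    b_length: int = 0  # length of sequence b (needed for '-' arithmetic)
    # working-coordinate anchor arrays (b on the orientation strand), built lazily
    _aw: np.ndarray | None = field(default=None, repr=False)

    def _arrays(self):
        if self._aw is None:
            rows = []
            for an in self.anchors:
                if self.orientation == "+":
                    rows.append((an.a_start, an.a_end, an.b_start, an.b_end))
                else:
                    rows.append(
                        (an.a_start, an.a_end, self.b_length - an.b_end, self.b_length - an.b_start)
                    )
            rows.sort()
            self._aw = np.asarray(rows, dtype=np.int64)
        return self._aw


@njit(cache=True)
def _extend_ungapped(a, b, a_s, a_e, b_s, min_identity, max_miss_streak):  # pragma: no cover
    """Extend an exact match [a_s,a_e)/[b_s,..) both ways under an identity floor."""
    length = a_e - a_s
    matches = length
    total = length
    # right
    i = a_e
    j = b_s + length
    streak = 0
    best_i = i
    best_m = matches
    best_t = total
    while i < a.size and j < b.size:
        m = 1 if (a[i] == b[j] and a[i] < 4) else 0
        matches += m
        total += 1
        streak = 0 if m else streak + 1
        if streak >= max_miss_streak or matches < min_identity * total:
            break
        i += 1
        j += 1
        if m:
            best_i = i
            best_m = matches
            best_t = total
    a_e = best_i
    matches = best_m
    total = best_t
    # left
    i = a_s - 1
    j = b_s - 1
    streak = 0
    best_i = a_s
    best_j = b_s
    best_m = matches
    best_t = total
    while i >= 0 and j >= 0:
        m = 1 if (a[i] == b[j] and a[i] < 4) else 0
        matches += m
        total += 1
        streak = 0 if m else streak + 1
        if streak >= max_miss_streak or matches < min_identity * total:
            break
        if m:
            best_i = i
            best_j = j
            best_m = matches
            best_t = total
        i -= 1
        j -= 1
    return best_i, a_e, best_j, best_m, best_t


def _anchors_one_strand(
    a_codes, b_codes, seed_len, min_identity, max_occ
) -> list[tuple[int, int, int, float]]:
    """(a_start, a_end, b_start_working, identity) anchors for one b strand."""
    av, avalid = kmer_values(a_codes, seed_len)
    bv, bvalid = kmer_values(b_codes, seed_len)
    if not len(av) or not len(bv):
        return []
    bpos = np.nonzero(bvalid)[0]
    bv = bv[bpos]
    order = np.argsort(bv, kind="stable")
    bv_sorted = bv[order]
    bpos_sorted = bpos[order]
    apos = np.nonzero(avalid)[0]
    avv = av[apos]
    left = np.searchsorted(bv_sorted, avv, side="left")
    right = np.searchsorted(bv_sorted, avv, side="right")
    cnt = right - left
    keep = (cnt > 0) & (cnt <= max_occ)
    pairs_a = np.repeat(apos[keep], cnt[keep])
    idx = np.concatenate(
        [np.arange(l, r) for l, r in zip(left[keep], right[keep])]
    ) if keep.any() else np.empty(0, dtype=np.int64)
    pairs_b = bpos_sorted[idx]
    if not len(pairs_a):
        return []
    diag = pairs_a - pairs_b
    order = np.lexsort((pairs_a, diag))
    pa = pairs_a[order]
    pb = pairs_b[order]
    dg = diag[order]
    # merge consecutive k-mer matches on one diagonal into exact runs
    runs = []
    s = 0
    for i in range(1, len(pa) + 1):
        if i == len(pa) or dg[i] != dg[s] or pa[i] != pa[i - 1] + 1:
            runs.append((int(pa[s]), int(pa[i - 1]) + seed_len, int(pb[s])))
            s = i
    anchors = []
    seen: set[tuple[int, int, int]] = set()
    for a_s, a_e, b_s in runs:
        ra_s, ra_e, rb_s, m, t = _extend_ungapped(
            a_codes, b_codes, a_s, a_e, b_s, min_identity, 4
        )
        key = (ra_s - rb_s, ra_s, ra_e)
        if key in seen:
            continue
        seen.add(key)
        anchors.append((ra_s, ra_e, rb_s, m / t if t else 0.0))
    # drop anchors contained in another anchor on the same diagonal (sweep by
    # ascending start: contained iff the end does not advance)
    anchors.sort(key=lambda r: (r[0] - r[2], r[0], -(r[1] - r[0])))
    out = []
    max_end: dict[int, int] = {}
    for a_s, a_e, b_s, ident in anchors:
        diag = a_s - b_s
        if a_e <= max_end.get(diag, -1):
            continue
        max_end[diag] = a_e
        out.append((a_s, a_e, b_s, ident))
    return out


def find_anchors(
    a: str,
    b: str,
    seed_len: int = DEFAULT_SEED_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_occ: int = DEFAULT_MAX_OCC,
) -> list[Anchor]:
    """Maximal exact matches >= seed_len on both strands, extended ungapped.

    Seeds occurring more than ``max_occ`` times in b (repeat-derived) are
    skipped.  Anchors report b intervals on the forward strand.
    """
    a_codes = encode(a)
    nb = len(b)
    anchors: list[Anchor] = []
    for strand in "+-":
        b_work = b if strand == "+" else revcomp(b)
        b_codes = encode(b_work)
        for a_s, a_e, b_s, ident in _anchors_one_strand(
            a_codes, b_codes, seed_len, min_identity, max_occ
        ):
            L = a_e - a_s
            if strand == "+":
                anchors.append(Anchor(a_s, a_e, b_s, b_s + L, "+", ident))
            else:
                anchors.append(Anchor(a_s, a_e, nb - (b_s + L), nb - b_s, "-", ident))
    anchors.sort(key=lambda x: (x.a_start, x.a_end))
    return anchors


@njit(cache=True)
def _chain_dp(a_s, a_e, b_s, b_e, w, max_gap, drift_free, lookback, overlap_slack):  # pragma: no cover
    n = a_s.size
    score = np.empty(n, dtype=np.float64)
    parent = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        best = w[i]
        bp = -1
        scanned = 0
        for j in range(i - 1, -1, -1):
            ga = a_s[i] - a_e[j]
            gb = b_s[i] - b_e[j]
            if ga > max_gap:
                break  # anchors sorted by a; everything earlier is farther
            scanned += 1
            if scanned > lookback:
                break
            if ga < -overlap_slack or gb < -overlap_slack:
                continue
            if gb > max_gap:
                continue
            if b_s[i] < b_s[j] or a_s[i] < a_s[j]:
                continue
            drift = ga - gb if ga > gb else gb - ga
            pen = 0.0
            if drift > drift_free:
                pen = 0.05 * (drift - drift_free)
            gmin = ga if ga < gb else gb
            if gmin > 0:
                pen += 0.01 * gmin
            cand = score[j] + w[i] - pen
            if cand > best:
                best = cand
                bp = j
        score[i] = best
        parent[i] = bp
    return score, parent


def chain_diagonals(
    anchors: list[Anchor],
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    max_gap: int = DEFAULT_MAX_GAP,
    a_seq_id: str = "A",
    b_seq_id: str = "B",
    b_length: int | None = None,
    lookback: int = 2000,
    min_score: float = 0.0,
    max_unaligned: int = 1500,
    a_n_runs: list[tuple[int, int]] | None = None,
    b_n_runs: list[tuple[int, int]] | None = None,
) -> list[OrthologousFragment]:
    """Chain anchors into non-overlapping orthologous fragments.

    Chains maximize total anchor weight (length x identity) minus gap/drift
    penalties; per-link drifts up to ``max_diag_drift`` are free, larger
    drifts (one-sided gaps left by insertions) are penalized linearly.
    Chains are split at links with more than ``max_unaligned`` nt unaligned
    on *both* sequences (no homology evidence bridges such a link, e.g.
    across an inversion), so a rearranged block inside a match becomes its
    own fragment — unless the gap is mostly assembly N on either sequence
    (``a_n_runs``/``b_n_runs``), where homology is merely unobservable.
    Fragments are selected greedily by score and kept only if
    they do not overlap a better fragment on sequence a; ties break by
    leftmost a coordinate.
    """
    if not anchors:
        return []
    if b_length is None:
        b_length = max(an.b_end for an in anchors)
    fragments: list[OrthologousFragment] = []
    for strand in "+-":
        sub = [an for an in anchors if an.strand == strand]
        if not sub:
            continue
        # work in coordinates where b advances with a
        if strand == "+":
            rows = sorted((an.a_start, an.a_end, an.b_start, an.b_end, i) for i, an in enumerate(sub))
        else:
            rows = sorted(
                (an.a_start, an.a_end, b_length - an.b_end, b_length - an.b_start, i)
                for i, an in enumerate(sub)
            )
        a_s = np.array([r[0] for r in rows], dtype=np.int64)
        a_e = np.array([r[1] for r in rows], dtype=np.int64)
        b_s = np.array([r[2] for r in rows], dtype=np.int64)
        b_e = np.array([r[3] for r in rows], dtype=np.int64)
        w = np.array([sub[r[4]].weight for r in rows], dtype=np.float64)
        score, parent = _chain_dp(
            a_s, a_e, b_s, b_e, w, max_gap, max_diag_drift, lookback, 50
        )
        used = np.zeros(len(rows), dtype=bool)
        order = np.argsort(-score, kind="stable")
        for end in order:
            if used[end] or score[end] < min_score:
                continue
            chain = []
            i = int(end)
            broken = False
            while i != -1:
                if used[i]:
                    broken = True
                    break
                chain.append(i)
                i = int(parent[i])
            if broken or not chain:
                continue
            chain.reverse()
            for i in chain:
                used[i] = True
            # split where both sequences have a long unanchored stretch,
            # unless the stretch is mostly assembly N on either side
            pieces: list[list[int]] = [[chain[0]]]
            for prev_i, i in zip(chain, chain[1:]):
                ga = int(a_s[i] - a_e[prev_i])
                gb = int(b_s[i] - b_e[prev_i])
                if min(ga, gb) > max_unaligned:
                    gap_a = (int(a_e[prev_i]), int(a_s[i]))
                    if strand == "+":
                        gap_b = (int(b_e[prev_i]), int(b_s[i]))
                    else:
                        gap_b = (b_length - int(b_s[i]), b_length - int(b_e[prev_i]))
                    if (
                        _interval_overlap_frac(gap_a, a_n_runs) < 0.5
                        and _interval_overlap_frac(gap_b, b_n_runs) < 0.5
                    ):
                        pieces.append([])
                pieces[-1].append(i)
            for piece in pieces:
                members = [sub[rows[i][4]] for i in piece]
                tot = sum(m.weight for m in members)
                lensum = sum(m.length for m in members)
                if tot < min_score:
                    continue
                frag = OrthologousFragment(
                    a_seq_id=a_seq_id,
                    b_seq_id=b_seq_id,
                    a_interval=(
                        min(m.a_start for m in members),
                        max(m.a_end for m in members),
                    ),
                    b_interval=(
                        min(m.b_start for m in members),
                        max(m.b_end for m in members),
                    ),
                    orientation=strand,
                    anchors=sorted(members, key=lambda m: m.a_start),
                    mean_identity=tot / lensum if lensum else 0.0,
                    score=tot,
                    chain_score=float(score[end]),
                    b_length=b_length,
                )
                fragments.append(frag)
    # one-to-one on a: greedy by score, secondary chains only if non-overlapping
    fragments.sort(key=lambda f: (-f.score, f.a_interval[0]))
    kept: list[OrthologousFragment] = []
    for f in fragments:
        s, e = f.a_interval
        if any(min(e, k.a_interval[1]) - max(s, k.a_interval[0]) > 50 for k in kept):
            continue
        kept.append(f)
    kept.sort(key=lambda f: f.a_interval[0])
    return kept


def _interval_overlap_frac(
    interval: tuple[int, int], runs: list[tuple[int, int]] | None
) -> float:
    """Fraction of ``interval`` covered by the (sorted) runs."""
    if not runs:
        return 0.0
    s, e = interval
    if e <= s:
        return 0.0
    cov = 0
    for rs, re in runs:
        cov += max(0, min(e, re) - max(s, rs))
        if rs >= e:
            break
    return cov / (e - s)


class LiftError(ValueError):
    pass


def lift_coordinate(
    fragment: OrthologousFragment,
    pos: int,
    max_gap: int = DEFAULT_MAX_GAP,
    gap_tolerance: float = 0.20,
) -> int | None:
    """Lift a position on a to the corresponding position on b, or None.

    Positions inside an anchor lift exactly; positions in inter-anchor gaps
    are interpolated only when the gap is length-concordant within
    ``gap_tolerance`` on both sequences and shorter than ``max_gap``,
    otherwise the position is unmapped (None).
    """
    s, e = fragment.a_interval
    if not s <= pos < e:
        raise LiftError(f"position {pos} outside fragment a interval [{s},{e})")
    arr = fragment._arrays()
    a_starts = arr[:, 0]
    idx = int(np.searchsorted(a_starts, pos, side="right")) - 1
    bw: float | None = None
    if idx >= 0 and pos < arr[idx, 1]:
        bw = float(arr[idx, 2] + (pos - arr[idx, 0]))
    else:
        # inter-anchor gap between idx and idx+1
        if idx < 0 or idx + 1 >= len(arr):
            bw = None
        else:
            ga = int(arr[idx + 1, 0] - arr[idx, 1])
            gb = int(arr[idx + 1, 2] - arr[idx, 3])
            big = max(ga, gb, 1)
            if ga > max_gap or gb > max_gap or abs(ga - gb) > gap_tolerance * big + 2:
                bw = None
            else:
                frac = (pos - int(arr[idx, 1])) / max(ga, 1)
                bw = float(arr[idx, 3] + frac * gb)
    if bw is None:
        return None
    bwi = int(round(bw))
    if fragment.orientation == "+":
        return bwi
    return fragment.b_length - 1 - bwi


def lift_flanked(
    fragment: OrthologousFragment, a_start: int, a_end: int
) -> tuple[int, int]:
    """b interval bracketing [a_start, a_end) via the nearest flanking anchors.

    Used to locate the orthologous ("empty") site of a candidate insertion:
    interior positions of an insertion have no orthologous base, so the site
    is delimited by lifting the closest anchored positions on each side.
    """
    arr = fragment._arrays()
    # working b for the last anchored position <= a_start
    idx = int(np.searchsorted(arr[:, 0], a_start, side="right")) - 1
    if idx >= 0:
        if a_start < arr[idx, 1]:
            left_w = int(arr[idx, 2] + (a_start - arr[idx, 0]))
        else:
            left_w = int(arr[idx, 3])
    else:
        left_w = int(arr[0, 2])
    jdx = int(np.searchsorted(arr[:, 1], a_end, side="left"))
    if jdx < len(arr):
        if arr[jdx, 0] <= a_end:
            right_w = int(arr[jdx, 2] + max(0, a_end - arr[jdx, 0]))
        else:
            right_w = int(arr[jdx, 2])
    else:
        right_w = int(arr[-1, 3])
    if right_w < left_w:
        left_w, right_w = right_w, left_w
    if fragment.orientation == "+":
        return left_w, right_w
    return fragment.b_length - right_w, fragment.b_length - left_w


def flip_fragment(fragment: OrthologousFragment) -> OrthologousFragment:
    """Swap the roles of a and b (for lifting b -> a)."""
    if fragment.orientation == "+":
        anchors = [
            Anchor(an.b_start, an.b_end, an.a_start, an.a_end, "+", an.identity)
            for an in fragment.anchors
        ]
        a_len = max(an.a_end for an in fragment.anchors)
    else:
        anchors = [
            Anchor(an.b_start, an.b_end, an.a_start, an.a_end, "-", an.identity)
            for an in fragment.anchors
        ]
        a_len = fragment.a_interval[1]
    return OrthologousFragment(
        a_seq_id=fragment.b_seq_id,
        b_seq_id=fragment.a_seq_id,
        a_interval=fragment.b_interval,
        b_interval=fragment.a_interval,
        orientation=fragment.orientation,
        anchors=sorted(anchors, key=lambda x: x.a_start),
        mean_identity=fragment.mean_identity,
        score=fragment.score,
        b_length=a_len,
    )


def map_genomes(
    a: str,
    b: str,
    a_seq_id: str = "A",
    b_seq_id: str = "B",
    *,
    seed_len: int = DEFAULT_SEED_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_diag_drift: int = DEFAULT_MAX_DIAG_DRIFT,
    max_gap: int = DEFAULT_MAX_GAP,
    max_occ: int = DEFAULT_MAX_OCC,
    min_score: float = 100.0,
) -> list[OrthologousFragment]:
    from ._align import find_n_runs

    anchors = find_anchors(a, b, seed_len=seed_len, min_identity=min_identity, max_occ=max_occ)
    return chain_diagonals(
        anchors,
        max_diag_drift=max_diag_drift,
        max_gap=max_gap,
        a_seq_id=a_seq_id,
        b_seq_id=b_seq_id,
        b_length=len(b),
        min_score=min_score,
        a_n_runs=[(s, e) for s, e, _ in find_n_runs(a)],
        b_n_runs=[(s, e) for s, e, _ in find_n_runs(b)],
    )


def fragments_to_table(fragments: list[OrthologousFragment]):
    """Fragment table (1-based inclusive coordinates in the file)."""
    import pandas as pd

    rows = [
        dict(
            a_seq=f.a_seq_id,
            a_start=f.a_interval[0] + 1,
            a_end=f.a_interval[1],
            b_seq=f.b_seq_id,
            b_start=f.b_interval[0] + 1,
            b_end=f.b_interval[1],
            orientation=f.orientation,
            mean_identity=round(f.mean_identity, 4),
            n_anchors=len(f.anchors),
        )
        for f in fragments
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "a_seq", "a_start", "a_end", "b_seq", "b_start", "b_end",
            "orientation", "mean_identity", "n_anchors",
        ],
    )


def fragments_to_json(fragments: list[OrthologousFragment]) -> list[dict]:
    return [
        dict(
            a_seq_id=f.a_seq_id,
            b_seq_id=f.b_seq_id,
            a_interval=list(f.a_interval),
            b_interval=list(f.b_interval),
            orientation=f.orientation,
            mean_identity=f.mean_identity,
            score=f.score,
            b_length=f.b_length,
            anchors=[
                [an.a_start, an.a_end, an.b_start, an.b_end, an.strand, an.identity]
                for an in f.anchors
            ],
        )
        for f in fragments
    ]


def fragments_from_json(data: list[dict]) -> list[OrthologousFragment]:
    out = []
    for d in data:
        anchors = [Anchor(*row[:4], row[4], row[5]) for row in d["anchors"]]
        out.append(
            OrthologousFragment(
                a_seq_id=d["a_seq_id"],
                b_seq_id=d["b_seq_id"],
                a_interval=tuple(d["a_interval"]),
                b_interval=tuple(d["b_interval"]),
                orientation=d["orientation"],
                anchors=anchors,
                mean_identity=d["mean_identity"],
                score=d["score"],
                b_length=d["b_length"],
            )
        )
    return out
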