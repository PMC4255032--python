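"""Scoring of pipeline calls against a simulation truth manifest.

Recall is measured over planted species-specific insertions (optionally
restricted to a minimum length), precision over accepted specific calls;
calls matching planted composite or solo-LTR events are not false
positives.  TSD recovery is exact-string: a planted TSD counts as recovered
only when the call reports the identical sequence, and plants without a
matching call count as misses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calls import CallSet, InsertionCall
from .simulate import TruthEvent, TruthManifest


def _interval(ev: TruthEvent, species: str):
    return ev.a_interval if species == "A" else ev.b_interval


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return min(a[1], b[1]) - max(a[0], b[0])


@dataclass
class ScoreReport:
    n_truth: int
    n_calls: int
    true_positives: int
    recall: float
    precision: float
    artifact_total: int
    artifact_flagged: int
    artifact_flag_rate: float
    artifact_leaked: int  # artifact plants accepted as specific calls
    tsd_total: int
    tsd_exact: int
    tsd_exact_rate: float
    solo_ltr_expected: bool = False
    solo_ltr_recovered: bool = False
    unmatched_truth: list = field(default_factory=list)
    false_positive_calls: list = field(default_factory=list)


def score_calls(
    callset: CallSet,
    manifest: TruthManifest,
    min_truth_len: int = 150,
    min_overlap_frac: float = 0.5,
) -> ScoreReport:
    """Match specific calls to planted events (greedy 1-to-1 by overlap)."""
    truth_specific: list[tuple[str, TruthEvent]] = []
    for ev in manifest.of_type("specific_A", "specific_B"):
        sp = "A" if ev.event_type == "specific_A" else "B"
        iv = _interval(ev, sp)
        if iv and iv[1] - iv[0] >= min_truth_len:
            truth_specific.append((sp, ev))
    # benign extra truth: composite and solo-LTR plants (calls matching them
    # are correct detections, just not part of the specific recall set)
    benign: list[tuple[str, TruthEvent]] = []
    for ev in manifest.of_type("composite"):
        for sp in "AB":
            if _interval(ev, sp):
                benign.append((sp, ev))
    for ev in manifest.of_type("solo_ltr_recombination"):
        benign.append(("B", ev))
        benign.append(("A", ev))

    calls = callset.specific()
    matched_truth: dict[int, InsertionCall] = {}
    used_calls: set[int] = set()
    pairs = []
    for ti, (sp, ev) in enumerate(truth_specific):
        iv = _interval(ev, sp)
        for ci, call in enumerate(calls):
            if call.carrier_species != sp or not call.filled_interval:
                continue
            ov = _overlap(iv, call.filled_interval)
            if ov >= min_overlap_frac * (iv[1] - iv[0]):
                pairs.append((ov, ti, ci))
    pairs.sort(key=lambda t: -t[0])
    for ov, ti, ci in pairs:
        if ti in matched_truth or ci in used_calls:
            continue
        matched_truth[ti] = calls[ci]
        used_calls.add(ci)
    # benign matches among the remaining calls
    for ci, call in enumerate(calls):
        if ci in used_calls or not call.filled_interval:
            continue
        for sp, ev in benign:
            iv = _interval(ev, sp)
            if iv is None or call.carrier_species != sp:
                continue
            ov = _overlap(iv, call.filled_interval)
            if ov > 0.3 * (iv[1] - iv[0]) or ov > 0.3 * call.length:
                used_calls.add(ci)
                break
    tp = len(matched_truth)
    fp_calls = [c for ci, c in enumerate(calls) if ci not in used_calls]
    recall = tp / len(truth_specific) if truth_specific else 1.0
    precision = tp / (tp + len(fp_calls)) if (tp + len(fp_calls)) else 1.0

    # artifact plants
    art_events = manifest.of_type("n_artifact")
    art_flagged = 0
    art_leaked = 0
    flagged = callset.with_status("artifact")
    for ev in art_events:
        sp = "A" if (ev.a_interval and ev.tsd) else "B"
        iv = ev.a_interval if sp == "A" else ev.b_interval
        # carrier side = the side holding real sequence (other side is the N run)
        if ev.a_interval and ev.b_interval:
            # infer: the N run was planted opposite the TE; check both sides
            hits = [
                c
                for c in flagged
                if c.filled_interval
                and (
                    (c.carrier_species == "A" and ev.a_interval and _overlap(ev.a_interval, c.filled_interval) > 0)
                    or (c.carrier_species == "B" and ev.b_interval and _overlap(ev.b_interval, c.filled_interval) > 0)
                )
            ]
        else:
            hits = []
        if hits:
            art_flagged += 1
        leak = [
            c
            for c in calls
            if c.filled_interval
            and (
                (c.carrier_species == "A" and ev.a_interval and _overlap(ev.a_interval, c.filled_interval) > 0.5 * (ev.a_interval[1] - ev.a_interval[0]))
                or (c.carrier_species == "B" and ev.b_interval and _overlap(ev.b_interval, c.filled_interval) > 0.5 * (ev.b_interval[1] - ev.b_interval[0]))
            )
        ]
        if leak:
            art_leaked += 1

    # TSD exact recovery over TSD-bearing specific plants
    tsd_total = tsd_exact = 0
    for ti, (sp, ev) in enumerate(truth_specific):
        if not ev.tsd:
            continue
        tsd_total += 1
        call = matched_truth.get(ti)
        if call is not None and call.tsd == ev.tsd:
            tsd_exact += 1

    solo_expected = bool(manifest.of_type("solo_ltr_recombination"))
    solo_recovered = any(
        getattr(c, "solo_ltr_event", None) is not None for c in callset.calls
    )
    unmatched = [
        (sp, _interval(ev, sp), ev.consensus_id)
        for ti, (sp, ev) in enumerate(truth_specific)
        if ti not in matched_truth
    ]
    return ScoreReport(
        n_truth=len(truth_specific),
        n_calls=len(calls),
        true_positives=tp,
        recall=recall,
        precision=precision,
        artifact_total=len(art_events),
        artifact_flagged=art_flagged,
        artifact_flag_rate=art_flagged / len(art_events) if art_events else 1.0,
        artifact_leaked=art_leaked,
        tsd_total=tsd_total,
        tsd_exact=tsd_exact,
        tsd_exact_rate=tsd_exact / tsd_total if tsd_total else 1.0,
        solo_ltr_expected=solo_expected,
        solo_ltr_recovered=solo_recovered,
        unmatched_truth=unmatched,
        false_positive_calls=[
            (c.carrier_species, c.filled_interval, c.insertion.consensus_id)
            for c in fp_calls
        ],
    )
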