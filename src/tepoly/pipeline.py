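"""End-to-end pipeline: annotate both genomes, map orthology, call and
characterize species-specific insertions, and summarize.

The stages mirror the comparative protocol: repeat annotation of each
genome against the consensus library; orthologous-fragment mapping; face-to-
face pairing and filled/empty-site calling; structural characterization
(TSDs, LTRs, solo-LTR recombination, composite decomposition, optional copy
number and transcriptome hits); and the divergence summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotate import AnnotatedInsertion, annotate_sequence
from .calls import CallSet, call_insertions
from .features import call_solo_ltr, decompose_composite, detect_ltrs, tsd_for_span
from .library import TEConsensus
from .orthomap import OrthologousFragment, map_genomes
from .summarize import DivergenceSummary, divergence_summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    annots_a: list[AnnotatedInsertion]
    annots_b: list[AnnotatedInsertion]
    fragments: list[OrthologousFragment]
    callset: CallSet
    summary: DivergenceSummary
    analyzed_bp: int


def characterize_calls(
    callset: CallSet,
    library: list[TEConsensus],
    genomes_a: dict[str, str],
    genomes_b: dict[str, str],
    *,
    ltr_superfamilies: tuple[str, ...] = ("ERV", "Gypsy", "Copia", "Bel-Pao"),
    min_ltr: int = 100,
) -> None:
    """Attach LTR pairs, solo-LTR events and composite decompositions in place."""
    by_id = {c.id: c for c in library}
    for call in callset.calls:
        if call.status not in ("specific", "composite"):
            continue
        ins = call.insertion
        carrier = genomes_a if call.carrier_species == "A" else genomes_b
        other = genomes_b if call.carrier_species == "A" else genomes_a
        genome = carrier[ins.seq_id]
        element_seq = genome[ins.start : ins.end]
        # LTR structure and solo-LTR recombination at the empty site
        cons = by_id.get(ins.consensus_id)
        if ins.superfamily in ltr_superfamilies and len(element_seq) >= 2 * min_ltr:
            call.ltr_pair = detect_ltrs(element_seq, min_ltr=min_ltr)
            if call.ltr_pair is not None:
                # the indel-block TSD of a two-LTR element facing a solo LTR is
                # the LTR-LTR microhomology; the element's real TSD flanks the
                # whole annotated span
                span_tsd, span_cls = tsd_for_span(genome, ins.start, ins.end, slack=3)
                if span_tsd:
                    call.tsd, call.tsd_class = span_tsd, span_cls
            if call.ltr_pair is not None and call.empty_window is not None:
                ws, we = call.empty_window
                other_seq = next(iter(other.values())) if len(other) == 1 else None
                # empty window was extracted from the fragment's b sequence
                for seq in ([other_seq] if other_seq else other.values()):
                    ev = call_solo_ltr(
                        call,
                        call.ltr_pair,
                        element_seq,
                        seq[ws:we],
                        empty_site_offset=ws,
                    )
                    if ev is not None:
                        call.solo_ltr_event = ev
                        call.status = "solo_ltr_counterpart"
                        break
        # composite decomposition: several consensi, or weak primary coverage
        consensi = {h.consensus_id for h in ins.components}
        primary_cov = ins.total_length / max(1, ins.end - ins.start)
        if len(consensi) > 1 or primary_cov < 0.8:
            if call.filled_interval:
                s, e = call.filled_interval
                comp = decompose_composite(genome[s:e], library)
                call.composite = comp
                if len({c[0] for c in comp.components}) > 1:
                    call.status = "composite"


def run_pair(
    genome_a: str,
    genome_b: str,
    library: list[TEConsensus],
    *,
    a_seq_id: str = "genomeA",
    b_seq_id: str = "genomeB",
    annotate_kwargs: dict | None = None,
    map_kwargs: dict | None = None,
    call_kwargs: dict | None = None,
    characterize: bool = True,
) -> PipelineResult:
    """Run the comparative pipeline on one genome pair."""
    annotate_kwargs = annotate_kwargs or {}
    map_kwargs = map_kwargs or {}
    call_kwargs = call_kwargs or {}
    logger.info("annotating %s (%d nt)", a_seq_id, len(genome_a))
    annots_a = annotate_sequence(genome_a, library, seq_id=a_seq_id, **annotate_kwargs)
    logger.info("annotating %s (%d nt)", b_seq_id, len(genome_b))
    annots_b = annotate_sequence(genome_b, library, seq_id=b_seq_id, **annotate_kwargs)
    logger.info("mapping orthologous fragments")
    fragments = map_genomes(
        genome_a, genome_b, a_seq_id=a_seq_id, b_seq_id=b_seq_id, **map_kwargs
    )
    logger.info(
        "%d fragments; %d/%d annotations", len(fragments), len(annots_a), len(annots_b)
    )
    callset = call_insertions(
        annots_a,
        annots_b,
        fragments,
        {a_seq_id: genome_a},
        {b_seq_id: genome_b},
        **call_kwargs,
    )
    if characterize:
        characterize_calls(
            callset, library, {a_seq_id: genome_a}, {b_seq_id: genome_b}
        )
    analyzed = sum(f.a_interval[1] - f.a_interval[0] for f in fragments)
    summary = divergence_summary(
        callset.specific(), shared_count=len(callset.shared), analyzed_bp=max(analyzed, 1)
    )
    return PipelineResult(
        annots_a=annots_a,
        annots_b=annots_b,
        fragments=fragments,
        callset=callset,
        summary=summary,
        analyzed_bp=analyzed,
    )
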