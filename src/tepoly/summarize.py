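"""Headline comparative statistics and report rendering.

Computes, from a set of insertion calls and shared-insertion counts, the
quantities a two-genome TE comparison reports: shared-insertion density per
Mb, per-species base pairs and percentages of the analyzed regions covered
by species-specific insertions, their combined contribution to interspecific
divergence, insertion length statistics, a genome-wide extrapolation from
the analyzed fraction, and the genomic context of each call relative to gene
models.  A transcription of the reference study's printed per-insertion
table ships with the package as a worked fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import pandas as pd


def load_reference_insertion_table() -> pd.DataFrame:
    """The bundled per-insertion reference table (27 rows)."""
    text = resources.files("tepoly.data").joinpath("specific_insertions.tsv").read_text()
    return pd.read_csv(StringIO(text), sep="\t", dtype={"tsd": "string"})


@dataclass
class DivergenceSummary:
    analyzed_bp_total: int
    shared_count: int
    specific_counts: dict[str, int]
    specific_bp: dict[str, int]
    specific_pct: dict[str, float]  # raw fractions of analyzed_bp, in percent
    specific_pct_rounded: dict[str, float]  # rounded to 2 decimals
    combined_pct_raw: float
    combined_pct_rounded: float  # sum of the per-species rounded percentages
    shared_density_per_mb: float
    shared_density_rounded: float  # nearest ten, as quoted in prose
    mean_specific_length: float
    min_specific_length: int
    max_specific_length: int


def _call_species(call) -> str:
    return getattr(call, "carrier_species", None) or call["carrier_species"]


def _call_length(call) -> int:
    if hasattr(call, "length"):
        return int(call.length)
    return int(call["length"])


def divergence_summary(calls, shared_count: int, analyzed_bp: int) -> DivergenceSummary:
    """Densities and per-species divergence contributions.

    ``calls`` is any iterable of records with ``carrier_species`` and
    ``length`` (attributes or mapping keys).
    """
    if analyzed_bp <= 0:
        raise ValueError("analyzed_bp must be positive")
    counts: dict[str, int] = {}
    bp: dict[str, int] = {}
    lengths = []
    for c in calls:
        sp = _call_species(c)
        ln = _call_length(c)
        counts[sp] = counts.get(sp, 0) + 1
        bp[sp] = bp.get(sp, 0) + ln
        lengths.append(ln)
    pct = {sp: 100.0 * v / analyzed_bp for sp, v in bp.items()}
    pct_rounded = {sp: round(v, 2) for sp, v in pct.items()}
    density = shared_count / (analyzed_bp / 1e6)
    return DivergenceSummary(
        analyzed_bp_total=analyzed_bp,
        shared_count=shared_count,
        specific_counts=counts,
        specific_bp=bp,
        specific_pct=pct,
        specific_pct_rounded=pct_rounded,
        combined_pct_raw=sum(pct.values()),
        combined_pct_rounded=round(sum(pct_rounded.values()), 2),
        shared_density_per_mb=density,
        shared_density_rounded=round(density / 10.0) * 10.0,
        mean_specific_length=sum(lengths) / len(lengths) if lengths else 0.0,
        min_specific_length=min(lengths) if lengths else 0,
        max_specific_length=max(lengths) if lengths else 0,
    )


def extrapolate_genome(
    avg_specific_per_species: float, fraction_analyzed: float
) -> dict[str, float]:
    """Genome-wide species-specific insertion estimate from the analyzed fraction.

    The band rounds the estimate down/up at one significant figure below the
    leading digit (e.g. 6,750 -> 6,500-7,000).
    """
    if not 0 < fraction_analyzed <= 1:
        raise ValueError("fraction_analyzed must be in (0, 1]")
    if avg_specific_per_species < 0:
        raise ValueError("average count must be >= 0")
    est = avg_specific_per_species / fraction_analyzed
    if est == 0:
        band = (0.0, 0.0)
    else:
        unit = 5 * 10 ** (math.floor(math.log10(est)) - 1)
        band = (math.floor(est / unit) * unit, math.ceil(est / unit) * unit)
    return dict(
        per_species=est,
        combined=2 * est,
        band_low=float(band[0]),
        band_high=float(band[1]),
    )


# ---------------------------------------------------------------------------
# genomic context
# ---------------------------------------------------------------------------


@dataclass
class GenomicContext:
    call_id: str
    location_class: str  # intron | intergenic
    gene_id: str | None
    distance_to_closest_exon_kb: float | None
    unbounded: bool = False  # nearest exon beyond the analyzed sequence end

    def distance_str(self) -> str:
        if self.distance_to_closest_exon_kb is None:
            return "NA"
        s = f"{self.distance_to_closest_exon_kb:.1f}"
        return f">{s}" if self.unbounded else s


def _load_gene_models(gff3):
    """(genes, exons) per seq id from a GFF3 path/string via gffutils."""
    import gffutils

    if hasattr(gff3, "read"):
        data = gff3.read()
    else:
        data = str(gff3)
    if "\t" not in data:  # a path
        db = gffutils.create_db(
            data, ":memory:", merge_strategy="create_unique", keep_order=True
        )
    else:
        db = gffutils.create_db(
            data, ":memory:", from_string=True, merge_strategy="create_unique",
            keep_order=True,
        )
    genes = []
    for g in db.features_of_type("gene"):
        exons = []
        for ex in db.children(g, featuretype="exon"):
            exons.append((ex.start - 1, ex.end))
        exons.sort()
        genes.append((g.seqid, g.start - 1, g.end, g.id, exons))
    return genes


def genomic_context(calls, gene_models, seq_lengths: dict[str, int] | None = None):
    """Classify calls as intronic/intergenic and measure exon distances.

    ``gene_models`` is a GFF3 path or string (gene/mRNA/exon features).  With
    no gene models every call is intergenic with an unbounded distance, as a
    draft annotation would report (">X" to the sequence end).
    """
    genes = _load_gene_models(gene_models) if gene_models else []
    out = []
    for c in calls:
        seq_id = c.insertion.seq_id if hasattr(c, "insertion") else c["seq_id"]
        s, e = (
            c.filled_interval
            if hasattr(c, "filled_interval") and c.filled_interval
            else (c["start"], c["end"])
        )
        call_id = (
            f"{c.carrier_species}_{c.insertion.element_id}"
            if hasattr(c, "insertion")
            else str(c.get("id", f"{seq_id}:{s}"))
        )
        mine = [g for g in genes if g[0] == seq_id]
        location = "intergenic"
        gene_id = None
        best = None  # (distance_nt, gene_id)
        for _, gs, ge, gid, exons in mine:
            if gs <= s and e <= ge and not any(min(e, xe) > max(s, xs) for xs, xe in exons):
                location = "intron"
                gene_id = gid
            for xs, xe in exons:
                if xe <= s:
                    d = s - xe
                elif xs >= e:
                    d = xs - e
                else:
                    d = 0
                if best is None or d < best[0] or (d == best[0] and xs < best[2]):
                    best = (d, gid, xs)
        if best is None:
            length = (seq_lengths or {}).get(seq_id)
            dist = round((length - e) / 1000.0, 1) if length else None
            out.append(GenomicContext(call_id, "intergenic", None, dist, unbounded=True))
        else:
            out.append(
                GenomicContext(
                    call_id,
                    location,
                    gene_id or best[1],
                    round(best[0] / 1000.0, 1),
                )
            )
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

_SPECIES_LABELS = {"A": "species A", "B": "species B"}


def summary_to_markdown(
    summary: DivergenceSummary,
    shared_by_superfamily: dict[str, int] | None = None,
    species_labels: dict[str, str] | None = None,
) -> str:
    lab = {**_SPECIES_LABELS, **(species_labels or {})}
    lines = [
        "# TE insertion polymorphism summary",
        "",
        f"Analyzed orthologous sequence: {summary.analyzed_bp_total / 1e6:.1f} Mb",
        f"Shared TE insertions: {summary.shared_count} "
        f"(~{summary.shared_density_rounded:.0f} TEs/Mb; raw "
        f"{summary.shared_density_per_mb:.1f})",
        "",
        "| species | specific insertions | total kb | % of analyzed |",
        "|---|---|---|---|",
    ]
    for sp in sorted(set(summary.specific_counts) | {"A", "B"}):
        n = summary.specific_counts.get(sp, 0)
        kb = summary.specific_bp.get(sp, 0) / 1000.0
        pct = summary.specific_pct_rounded.get(sp, 0.0)
        lines.append(f"| {lab.get(sp, sp)} | {n} | {kb:.1f} | {pct:.2f} |")
    lines += [
        "",
        f"Combined TE contribution to divergence: {summary.combined_pct_rounded:.2f}% "
        f"(sum of rounded per-species values; raw {summary.combined_pct_raw:.2f}%)",
        f"Specific insertion length: mean {summary.mean_specific_length:.0f} nt, "
        f"range {summary.min_specific_length}-{summary.max_specific_length} nt",
    ]
    if shared_by_superfamily:
        lines += ["", "| superfamily | shared insertions |", "|---|---|"]
        for fam in sorted(shared_by_superfamily):
            if fam != "total":
                lines.append(f"| {fam} | {shared_by_superfamily[fam]} |")
        lines.append(f"| total | {shared_by_superfamily.get('total', 0)} |")
    return "\n".join(lines) + "\n"


def summary_to_dict(summary: DivergenceSummary) -> dict:
    from dataclasses import asdict

    return asdict(summary)


def feature_table(calls, contexts=None) -> pd.DataFrame:
    """Per-call feature table mirroring the reference study's layout."""
    ctx = {c.call_id: c for c in contexts} if contexts else {}
    rows = []
    for c in calls:
        call_id = f"{c.carrier_species}_{c.insertion.element_id}"
        g = ctx.get(call_id)
        rows.append(
            dict(
                identifier=call_id,
                species=c.carrier_species,
                superfamily=c.insertion.superfamily,
                length_nt=c.length,
                tsd=c.tsd or "",
                tsd_class=c.tsd_class,
                status=c.status,
                copy_number_total=getattr(c, "copy_number_total", None),
                copy_number_high=getattr(c, "copy_number_high", None),
                transcriptome_hits=getattr(c, "transcriptome_hits", None),
                position_class=g.location_class if g else None,
                distance_kb=g.distance_str() if g else None,
            )
        )
    return pd.DataFrame(rows)
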