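"""TE consensus library: model, IO and low-complexity masking.

A library is a list of :class:`TEConsensus` records read from FASTA, with
the classification carried either in the header (``id#superfamily``, the
RepeatMasker-style dialect) or in a sidecar TSV (columns ``id``, ``class``,
``order``, ``superfamily``); the sidecar wins on conflict.  Superfamily
tokens are validated against the Wicker-style vocabulary shipped with the
package.  Low-complexity masking uses a DUST-style triplet over-representation
score; annotation hits falling entirely inside masked intervals are discarded
downstream, which stands in for the exclusion of simple repeats from the TE
census.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._align import encode, kmer_values

logger = logging.getLogger(__name__)

_VALID_BASES = set("ACGTNacgtn")


def superfamily_vocabulary() -> dict[str, tuple[str, str]]:
    """Mapping superfamily token -> (class, order) from the bundled table."""
    text = resources.files("tepoly.data").joinpath("superfamilies.tsv").read_text()
    vocab: dict[str, tuple[str, str]] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        vocab[row["token"]] = (row["te_class"], row["order"])
    return vocab


@dataclass
class TEConsensus:
    """One consensus entry of the TE library."""

    id: str
    superfamily: str
    sequence: str
    is_autonomous: bool = False
    declared_ltr_length: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 50:
            raise ValueError(f"consensus {self.id!r}: sequence shorter than 50 nt")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"consensus {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )
        self.sequence = self.sequence.upper()
        if self.declared_ltr_length is not None and self.declared_ltr_length <= 0:
            raise ValueError(f"consensus {self.id!r}: declared_ltr_length must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ComplexityMask:
    """Sorted, non-overlapping low-complexity intervals of one sequence."""

    seq_id: str
    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev = -1
        for s, e in self.intervals:
            if s >= e or s < prev:
                raise ValueError("mask intervals must be sorted and non-overlapping")
            prev = e

    def contains(self, pos: int) -> bool:
        for s, e in self.intervals:
            if s <= pos < e:
                return True
            if s > pos:
                break
        return False

    def covers(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely inside one masked interval."""
        for s, e in self.intervals:
            if s <= start and end <= e:
                return True
            if s >= end:
                break
        return False

    def position_flags(self, length: int) -> np.ndarray:
        flags = np.zeros(length, dtype=bool)
        for s, e in self.intervals:
            flags[s:e] = True
        return flags


def _parse_sidecar(path: str | Path) -> dict[str, dict[str, str]]:
    meta: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["id"]] = row
    return meta


def read_library(
    path: str | Path, sidecar: str | Path | None = None
) -> list[TEConsensus]:
    """Read a consensus library from FASTA (+ optional classification sidecar).

    Headers of the form ``id#superfamily`` carry the classification; a sidecar
    TSV overrides it.  Duplicate ids and unknown superfamily tokens are
    rejected.
    """
    vocab = superfamily_vocabulary()
    meta = _parse_sidecar(sidecar) if sidecar else {}
    entries: list[TEConsensus] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        superfamily = None
        if "#" in name:
            name, superfamily = name.split("#", 1)
            superfamily = superfamily.split("/")[0]
        row = meta.get(name)
        if row is not None and row.get("superfamily"):
            superfamily = row["superfamily"]
        if superfamily is None:
            raise ValueError(
                f"record {name!r}: no superfamily in header or sidecar"
            )
        if superfamily not in vocab:
            raise ValueError(
                f"record {name!r}: unknown superfamily {superfamily!r}; "
                f"allowed tokens: {', '.join(sorted(vocab))}"
            )
        if name in seen:
            raise ValueError(f"duplicate consensus id {name!r} in library")
        seen.add(name)
        seq = str(rec.seq)
        if not seq or set(seq) - _VALID_BASES:
            raise ValueError(f"malformed FASTA record {name!r}: invalid sequence")
        is_auto = False
        ltr_len = None
        if row is not None:
            is_auto = row.get("is_autonomous", "").lower() in {"1", "true", "yes"}
            if row.get("ltr_length"):
                ltr_len = int(row["ltr_length"])
        entries.append(
            TEConsensus(
                id=name,
                superfamily=superfamily,
                sequence=seq,
                is_autonomous=is_auto,
                declared_ltr_length=ltr_len,
            )
        )
    if not entries:
        logger.warning("library %s contains no records", path)
    return entries


def write_library(
    library: list[TEConsensus], path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Write a library as FASTA with ``id#superfamily`` headers (+ optional sidecar)."""
    vocab = superfamily_vocabulary()
    records = [
        SeqRecord(Seq(c.sequence), id=f"{c.id}#{c.superfamily}", description="")
        for c in library
    ]
    SeqIO.write(records, str(path), "fasta")
    if sidecar:
        with open(sidecar, "w") as fh:
            fh.write("id\tclass\torder\tsuperfamily\tis_autonomous\tltr_length\n")
            for c in library:
                cls, order = vocab[c.superfamily]
                fh.write(
                    f"{c.id}\t{cls}\t{order}\t{c.superfamily}\t"
                    f"{int(c.is_autonomous)}\t{c.declared_ltr_length or ''}\n"
                )


def mask_low_complexity(
    seq: str, window: int = 64, threshold: float = 2.0, seq_id: str = "seq"
) -> ComplexityMask:
    """Flag low-complexity/simple-repeat intervals with a DUST-style score.

    The score of a window is sum(c_t * (c_t - 1) / 2) over triplet counts
    ``c_t``, normalised by (number of triplets - 1).  Windows are evaluated at
    half-window steps; windows whose score exceeds ``threshold`` are flagged
    and merged.  A homopolymer scores ~window/2, a uniform random sequence
    ~0.5.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    if len(seq) < window:
        return ComplexityMask(seq_id=seq_id, intervals=[])
    codes = encode(seq)
    trip, valid = kmer_values(codes, 3)
    trip = np.where(valid, trip, 64)  # invalid triplets into a sink bin
    step = max(window // 2, 1)
    starts = list(range(0, len(seq) - window + 1, step))
    if starts[-1] != len(seq) - window:
        starts.append(len(seq) - window)
    flagged: list[tuple[int, int]] = []
    ntrip = window - 2
    for s in starts:
        counts = np.bincount(trip[s : s + ntrip], minlength=65)[:64]
        score = float(np.sum(counts * (counts - 1) // 2)) / max(ntrip - 1, 1)
        if score > threshold:
            if flagged and s <= flagged[-1][1]:
                flagged[-1] = (flagged[-1][0], s + window)
            else:
                flagged.append((s, s + window))
    return ComplexityMask(seq_id=seq_id, intervals=flagged)
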