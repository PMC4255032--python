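# Methods

`tepoly` detects transposable-element (TE) insertions that are present in one
of two closely related genomes but absent at the orthologous site of the
other, characterizes them structurally, and quantifies the contribution of
transposition to interspecific genome divergence.  The design follows the
comparative protocol used for pairs of genomes a few million years apart
(on the order of 98–99% nucleotide identity), such as the two extant
coelacanth species: the unit of evidence is a "filled" site in one genome
facing an "empty" site in the other.

## Pipeline model and assumptions

1. **Repeat annotation** (`tepoly.annotate`).  Each genome is annotated
   against a TE consensus library by seed-and-extend local alignment: exact
   k-mer anchors (default k = 12, both strands), clustered by diagonal, are
   extended with a banded affine x-drop DP (match +1, mismatch −2, gap open
   −5, gap extend −1, x-drop 20, band half-width 30 — BLASTN-like scores).
   Hit identity is recomputed from a full affine-gap global alignment of the
   final intervals under the same scoring; a unit-cost edit distance would
   convert mismatch runs into indel pairs and overestimate identity on
   divergent copies by ~0.02.  Census filters retain hits of length ≥ 100 nt
   and divergence to the consensus ≤ 20% (both inclusive).  Close hits
   matching contiguous parts of one consensus on one strand (genomic gap
   ≤ 5 kb, consensus coordinates advancing with ≤ 50 nt overlap) are merged
   transitively into a single insertion record, so a copy fragmented by the
   local aligner is counted once.  Divergence is the raw mismatch fraction
   over aligned non-gap columns; no multiple-hit correction is applied by
   default, matching how copy–consensus divergence thresholds are commonly
   used in repeat censuses.
2. **Low-complexity masking** (`tepoly.library.mask_low_complexity`).  A
   DUST-style triplet over-representation score (window 64 nt, threshold
   2.0, evaluated at half-window steps) flags simple repeats; anchors inside
   the mask are skipped and hits entirely within it are discarded.  tRNA/rRNA
   pseudogene exclusion is delegated to the library content itself.
3. **Orthologous mapping** (`tepoly.orthomap`).  Anchors are maximal exact
   matches ≥ 20 nt extended ungapped while cumulative identity stays ≥ 0.95
   (mismatch streaks ≤ 3); seeds occurring more than 16 times in the target
   are skipped as repeat-derived.  Anchors are chained by a gap-bounded
   dynamic program maximizing summed anchor weight (length × identity):
   links allow gaps up to 10 kb per side; diagonal drift up to 200 nt is
   free and larger drifts — the one-sided gaps that insertions leave — are
   penalized linearly (0.05/nt beyond the allowance, plus 0.01/nt of
   two-sided gap).  A hard per-link drift cutoff would break the chain at
   every multi-kb insertion and destroy empty-site liftover, which is why
   drift is penalized rather than forbidden.  Chains are split only where
   more than 1.5 kb is unanchored on *both* sequences (no homology evidence,
   e.g. an inversion) and the gap is not dominated by assembly N runs.
   Fragments are selected greedily by score, one-to-one on the first genome.
   Liftover interpolates between bracketing anchors only when the
   inter-anchor gap is length-concordant within 20% on both sequences;
   otherwise the position is unmapped, which prevents false empty-site
   calls inside rearrangements.
4. **Insertion calling** (`tepoly.calls`).  Annotations of the two genomes
   are paired "face to face" through the fragments: same superfamily and
   reciprocal overlap ≥ 0.5 after liftover, matched 1-to-1 greedily by
   overlap.  Unpaired annotations become candidates.  Each candidate's
   empty window (lifted bracketing positions ± 500 nt flank) is screened
   for an N run covering ≥ 90% of its span whose length matches the
   candidate within ±10% — such sites are draft-assembly artifacts, flagged
   and excluded from specific calls.  Remaining candidates are verified by a
   global affine-gap alignment (match +1, mismatch −2, open −6, extend −1)
   of the filled window against the empty window; the insertion is the
   single maximal block where the filled sequence advances and the empty one
   does not, required to reach 100 nt (consistent with the annotation
   filter).  Candidates without such a block — typically copies annotated in
   one genome but missed in the other — are rejected (the site is in fact
   filled in both species).  Flanking alignment identity must reach 0.90 on
   both sides or the call is kept but flagged unrefined.  For DNA
   transposons an "insertion" in one species is reported as such even though
   excision in the other species is indistinguishable.
5. **Structural features** (`tepoly.features`).  The TSD is the longest
   exact duplication framing the element (2–25 nt).  Because the refinement
   aligner can slide the indel block anywhere within the target-site repeat,
   the duplication is reassembled from the two slide directions of the gap;
   when a lineage substitution immediately at the insertion edge shifts the
   optimal gap by a base or two, a fallback search anchored on the
   annotation boundaries (±2 nt slack, duplication length constrained by the
   indel length) recovers it.  Pure homopolymer A/T "duplications" of ≥ 5 nt
   are demoted to poly-A context (a poly-A target site otherwise always
   masquerades as a TSD); flanks are classified poly-A at ≥ 80% A (or T)
   over 20 nt and AT-rich at ≥ 85% A+T over 30 nt.  LTRs/TIRs are found by
   locally aligning the two element ends (windows up to 1.5 kb; accepted at
   length ≥ 100 nt, identity ≥ 0.80, ends within 50 nt of the termini).  A
   solo-LTR recombination event is called when the orthologous empty site of
   a two-LTR element aligns to one LTR at identity ≥ 0.90 and length within
   ±10%, with the same TSD string flanking both structures (searched within
   3 nt of the aligned solo boundaries to absorb alignment end wobble).
   For an LTR element facing a solo LTR, the indel-block "TSD" is actually
   the LTR–LTR microhomology, so the element's TSD is taken from the full
   annotated span instead.  Composite insertions (several consensi, or
   primary consensus covering < 80%) are decomposed by greedy highest-score
   non-overlapping tiling of library hits, with nested TSD search per
   component and a declared 60% coverage floor below which the decomposition
   is reported partial.  Copy numbers use the classical family filters
   (hit length ≥ 80% of the query, identity ≥ 80%; high-identity count at
   ≥ 98%; overlapping hits collapsed to the best per locus), transcriptome
   representation counts transcripts with a hit ≥ 80 nt at ≥ 95% identity,
   and subfamilies are single-linkage clusters at ≥ 98% pairwise global
   identity.
6. **Summaries** (`tepoly.summarize`).  Shared density = shared count /
   analyzed Mb (reported raw and rounded to the nearest ten); per-species
   specific percentages are rounded to two decimals and their sum is
   reported both ways (sum-of-rounded and raw); kb to one decimal.  The
   genome-wide extrapolation divides the mean per-species specific count by
   the analyzed genome fraction and reports a band rounded down/up at half
   of the leading-digit unit (6,750 → 6,500–7,000).  The analyzed-bp
   denominator is the orthologous-fragment total, not the raw input total.
   Genomic context classifies calls as intronic (strictly inside a gene,
   overlapping no exon) or intergenic, with distance to the closest exon
   boundary in kb (one decimal; ties to the lower coordinate; ">X" when the
   sequence end truncates the search).

## The synthetic genome pair

`tepoly.simulate` generates the study conditions the pipeline is validated
under.  Defaults: 1 Mb ancestor at GC 0.42; 540 shared TE copies per Mb
planted in the ancestor as 3′-anchored fragments (log-normal lengths, mean
≈ 290 nt, range 100–1,500 nt, divergence to consensus uniform in 2–18%) —
matching a repeat census in which shared elements are mostly old, short
fragments covering ~16% of the sequence; a pairwise substitution rate of
1.3% (half applied to each lineage; the printed interspecific identity is
the pairwise figure) with small indels at 1/10 that rate (geometric lengths,
mean 3 nt, applied outside planted elements); 100 species-specific
insertions per species planted *after* the split (log-normal lengths fitted
to the 27 reference insertion lengths, clipped to 225–5,091 nt; LINEs
5′-truncated; divergence to consensus 0–5%; TSDs 2–10 nt copied from the
target site; 8% of LINE plants land in a poly-A context instead of leaving
a TSD); 20 N-stretch artifact mimics (a TE insertion in one genome faced by
an equal-length N run in the other); one ERV (LTR 462 nt, internal region
4,167 nt, per-copy divergence 0.5% giving ~99% LTR–LTR identity) whose
orthologous site carries the programmed recombination product, a solo LTR
sharing the element's TSD; and one composite insertion (SINE flanked by two
direct-orientation SINEs).

Two deliberate idealizations make the manifest a well-defined oracle for
exact-string TSD scoring: a guard base on each side of a planted element is
adjusted whenever a chance extension would lengthen the apparent
duplication (so the planted TSD *is* the maximal duplication), and the
ERV/solo-LTR pair's four target-site bases are forced equal in the two
genomes (equivalent to conditioning on no lineage substitution in the
TSD).  Consensus sequences are synthetic random sequences at a fixed
internal seed; they model copy–consensus divergence, not real TE sequence
composition.

What the simulator does not emulate: substitution-rate heterogeneity and
CpG effects, transposition bursts and realistic copy-age distributions,
satellite and segmental duplication, gene conversion, and real assembly
error beyond N runs.  Passing the benchmark therefore demonstrates the
bookkeeping and detection logic under the stated divergence and density
conditions, not performance on real draft assemblies.

## Evaluation against truth

Specific calls are matched to planted events 1-to-1, greedily by overlap,
requiring ≥ 50% of the planted insertion covered.  Calls matching the
composite or solo-LTR plants are correct detections outside the specific
recall set.  Recall is measured over planted specific insertions ≥ 150 nt;
precision over all accepted specific calls.  TSD recovery is exact-string
over all TSD-bearing specific plants, with unmatched plants counted as
misses.  At the default conditions the pipeline reaches recall 0.96–0.99,
precision ≥ 0.99, artifact flagging 20/20 and TSD recovery 0.93–0.98 across
seeds (about 20 s on one CPU); `scripts/acceptance.py` recomputes these
from scratch.

## Known limitations

- Two same-family insertions planted independently at near-identical
  orthologous positions in the two species (< ~100 nt apart, closer than
  the local anchor spacing) cannot be separated from a shared insertion by
  alignment alone; they account for the few recall misses in the benchmark.
  The manual protocol this automates has the same blind spot.
- Interpolated liftover is approximate between anchors; empty-site
  positions are only anchored to the bracketing exact matches.
- The merge rule for split hits is a declared approximation of
  element-number joining in standard repeat annotators; its gap and overlap
  defaults (5 kb / 50 nt) are not fitted to data.
- Superfamily assignment comes entirely from the library's classification
  metadata; there is no protein-level or de novo classification.
- Multi-sequence inputs are mapped pairwise (every a-record against every
  b-record), which is quadratic and intended for BAC-versus-scaffold scale,
  not whole multi-Gb assemblies.
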