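# Methods

## The repeat model

A tandem amino-acid repeat (homopolymeric tract, homopeptide) is a region
of a protein dominated by consecutive occurrences of one residue, the
*main* residue. Such tracts arise from trinucleotide repeats generated
chiefly by replication slippage, mutate in length far faster than ordinary
sequence, and are rarely perfect in practice, so the detector models
imperfection explicitly. A repeat is an interval of the protein that

1. contains an uninterrupted *core* of at least `min_core_length` main
   residues (default **5**),
2. begins and ends on the main residue,
3. contains no internal run of non-main residues longer than
   `max_nonmain_run` (default **5**), and
4. has main-residue fraction (*purity*) of at least `min_main_fraction`
   (default **0.70**).

Purity 1 marks a perfect repeat. The three defaults are the conventional
settings for this analysis family; all are exposed on `DetectorParams`.
The 0.70 bound is treated as inclusive — "minimum percentage 70 %" reads
as attainable — with a `1e-9` slack on the floating-point comparison so a
window of exactly 70 % main residues (e.g. 14/20) always passes.

The unknown residue `X` can never be a main residue and counts as non-main
wherever it appears. Internal stop characters are a hard error in strict
parsing mode and a skip-with-warning otherwise; selenoproteins and other
non-standard letters are likewise flagged and skipped rather than guessed
at. All residue and codon coordinates are 0-based, half-open.

## Detection semantics

`detect_repeats` reports, per main residue, every interval satisfying the
four constraints that is **maximal under inclusion**, then reduces
overlapping or touching same-residue intervals to a single annotation per
biological tract (the longest is kept; ties go to the left-most; the
reduction is applied greedily in length-descending, start-ascending order
so the result is deterministic). Annotations of *different* main residues
may overlap — a `DEDEDE`-like stretch can legitimately carry a polyD and a
polyE annotation at once — because per-residue-type counts are tallied
independently.

Maximality is computed exactly: candidate endpoints are main-residue
positions, split into blocks separated by non-main gaps longer than
`max_nonmain_run` (no valid interval can span such a barrier); within a
block all endpoint pairs are screened and dominated intervals removed by a
sweep. We deliberately do *not* define the reported interval by greedy
block-by-block extension of each core, although `extend_core` exposes that
classic rule for single cores: greedy extension can stall on
"fail-then-recover" flanks where absorbing one insertion block drops the
window below the purity floor while absorbing two restores it
(`AAAAARRRRARAAAARAAAA` has a valid window covering all 20 residues at
purity exactly 0.70 that single-step absorption never reaches). The
inclusion-maximal definition is algorithm-independent, and the test suite
pins it against a brute-force interval enumeration on tens of thousands of
random sequences.

Two consequences of the per-tract reduction are worth knowing. First,
merging two maximal intervals is never itself valid (a valid union would
contradict the maximality of its parts), so the reduction only ever drops
intervals. Second, coverage is monotone in the purity threshold *before*
the reduction (lowering `min_main_fraction` only grows the maximal
intervals) but not necessarily after it, because a longer low-threshold
interval can displace two shorter ones; the property tests therefore
assert monotonicity at the maximal-interval stage.

There is no upper bound on repeat length.

## PLP — codon purity

For a repeat of length *n* residues with its in-frame codons available,
**PLP** is the length of the longest run of *identical* codons encoding
the main residue, divided by *n*. PLP = 1 means the tract is encoded by a
single repeated codon throughout — the signature of a young tract produced
by recent slippage — and decays towards 1/n as point mutations and
synonymous codon turnover accumulate. Codons at ambiguous positions
(unknown residue, `N` in the codon, or a tolerated translation mismatch)
break pure runs and can never extend one. The denominator is always the
full repeat length, so an imperfect repeat cannot reach PLP = 1.

CDS pairing strips one terminal stop codon when present, splits the
remainder in frame 0 and verifies the standard-code translation against
the protein; by default zero mismatches are tolerated (`max_mismatch`
relaxes this for draft assemblies, marking mismatched positions ambiguous
rather than trusting either sequence).

## Isoform selection

One protein per gene: the longest, with ties broken to the
lexicographically smallest protein identifier so the choice is
reproducible. The operation is idempotent and order-stable.

## Orthology

Orthologs are inferred as reciprocal best hits (RBH) from externally
produced 12-column tabular similarity searches. Per query the best subject
is the one with the smallest E-value **strictly below** the threshold
(default 1e-20; an E-value exactly at the threshold is rejected), ties
broken by larger bitscore then lexicographic subject id; self-hits are
ignored. A pair enters the table only if each member is the other's best
hit. The reference-anchored table keeps, by default, only rows filled in
every species, mirroring a single fully-orthologous comparison set; a flag
retains partial rows instead.

## Conservation on codon alignments

The pipeline consumes codon-based nucleotide alignments (gaps in
codon-sized chunks, frame preserved) produced by an external aligner; a
validator enforces the codon-alignment invariants and, optionally, that
each row ungaps to its CDS. Repeats are mapped to residue-column intervals
(exact round-trip guaranteed), and two repeats in two species are
*conserved counterparts* when they are the same amino-acid type and their
column intervals share at least one codon column. Because residue columns
fix the reading frame, a repeated nucleotide tract read in different
frames in two species (polyP via CCG vs polyA via GCC, say) surfaces as
different amino acids and is never called conserved — the type test
enforces the frame rule.

Per reference repeat the classifier records a presence vector over the
other species of its ortholog row and assigns one of three classes:
**species-only** (no counterpart in any compared species, after removing
the designated close relative of the reference — by default mouse for
human, human for mouse, zebra finch for turtle, turtle for zebra finch,
nobody for the anole or frog — so that a single close sister taxon does
not mask lineage-specific gains), **conserved-in-all**, or
**conserved-in-k** otherwise. Presence is boolean per species: a reference
repeat overlapping two distinct repeats in one ortholog counts once. The
three classes partition the catalog by construction. Reference proteins
lacking an alignment go to a skip report, not to an exception.

For gene families compared across clades, repeats are clustered per gene:
the clade member available for the most genes anchors the clusters, each
non-anchor repeat joins the first same-type overlapping cluster or seeds
an anchorless one, and a cluster is **clade-common** exactly when it
contains every *available* clade species — species without a sequence for
the gene ("N/A") are skipped, not counted as absent. Anchorless clusters
are necessarily non-clade-common (the anchor lacks them). A clade with a
single available species yields an undefined flag rather than a vacuous
"common". Repeats spanning trimmed alignment ends are compared on the
surviving columns.

## Functional groups and GC

Proteins are assigned to four non-redundant groups by case-insensitive
substring matching of keyword lists against GO term *names*, in priority
order with hierarchical exclusion (first match wins): Transcription
factor/Development (transcription, development, genesis, differentiation);
Signal (signal transduction, receptor, response, transport, membrane);
Metabolism (metabolic, transferase, catabolic, biosynthetic, protein
translation, protein modification, protein folding, proteolysis); then
Others, including unannotated proteins. The keyword lists are plain data
and can be replaced for other ontology releases. Annotations are keyed on
one well-annotated species and propagated across each ortholog row, on the
assumption that orthologs share function. The per-group repeat frequency
is (repeats in the group's proteins) / (proteins in the group).

GC content is (G+C)/(A+C+G+T) with `N` excluded from both sides.
GC profiles bin coding sequences into half-open percent intervals (last
bin closed; deciles by default) for two populations: all orthologous
coding regions, and repeat-containing proteins (RCPs) with the codons
under every repeat interval excised first, isolating whatever GC signal
remains once the repeat-encoding trinucleotide runs themselves are
removed.

## Statistics

Length distributions are compared with the two-sided two-sample rank-sum
test in its tie-corrected normal approximation (no continuity correction,
so identical samples give p = 1 and the statistic is antisymmetric under
swapping groups); the tests cross-check it against exact permutation
enumeration at small n. Species-only proportions are compared pairwise
with the two-sided Fisher exact test on (species-only, not-species-only)
2×2 tables, cross-checked against a direct hypergeometric tail sum.

Positional classes cut each protein into terciles and classify a repeat
by its midpoint (N-terminal, middle, C-terminal) — the simplest
deterministic rule; per-residue proportions sum to 1.

Per-type summary means are displayed to one decimal in TSV output; raw
values are kept in memory. "Mean core" averages each repeat's *longest*
uninterrupted tract.

## The synthetic-data generator

The generator emulates every input the pipeline consumes — paired
protein/CDS FASTA, 12-column hit tables, codon alignments, GO tables,
clade gene-fragment sets — with internally consistent planted truth, so
each stage (and the pipeline end to end) can be verified offline against
known answers. Design guarantees:

* **Exact recoverability.** Planted tracts keep their main residue out of
  the flanking `max_nonmain_run + 1` positions, so no valid extension can
  cross the flank (a gap of 6 already violates the insertion bound);
  background sequence is kept core-free (no run reaches
  `min_core_length`) by per-position rejection. The planted interval is
  therefore the unique maximal interval the detector can report.
* **Family alignments** are built column-wise with per-species run
  tracking, background and fill letters drawn from an alphabet excluding
  every planted (and decoy) residue. Species-specific insertions become
  gap columns elsewhere; gaps are codon-sized by construction. Family
  tracts are perfect, single-codon repeats (the proteome generator covers
  imperfection and codon skew).
* **Frame-shift decoys** place, at the same columns, the main codon and
  its frame-shifted reading (CCG/GCC, GGC/GCG, CAG/AGC), so the same
  repeated nucleotide pattern translates as two amino acids — classifiers
  must never call these conserved.
* **Hit tables** carry the planted RBH pairs at E ≈ 1e-40 plus decoys that
  are either above threshold (1e-19) or strong but non-reciprocal.
* **GO tables** draw term names containing the planted group's keywords;
  adversarial extras come only from lower-priority groups, so the planted
  label remains the unique correct assignment.
* Everything is driven by one `numpy` Generator; the same seed gives
  byte-identical FASTA/TSV output.

An optional per-residue point-mutation rate inside planted tracts stresses
the detector; truth intervals are then kept as planned, and only coverage
(not exact coordinates) is asserted.

What the generator does **not** emulate: realistic phylogenetic sequence
evolution (no substitution model, no indel process beyond planned gaps),
genome-quality artefacts (assembly gaps, frameshifts, low-complexity
miscalls), paralogy and gene duplication, alternative splicing, or
realistic GO term co-occurrence structure. Passing the synthetic battery
therefore demonstrates the correctness of the algorithms under their
stated definitions, not detector robustness on noisy draft proteomes —
on real data, repeat counts are known to vary between detectors and with
assembly quality.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: 10⁴ random
sequences (length ≤ 40, 4-letter alphabet) for detector/oracle
equivalence, 1000 seeded trials each for PLP recovery, conservation
classification and GO tables, 200 four-species families for RBH, a
200-protein synthetic proteome for the scan summaries, and the three
pipeline presets (40 proteins; 8 six-species families; 4 genes across 8
species in 3 clades). The full battery completes in well under a minute.
The only tolerances in play are the `1e-9` purity slack and exact equality
everywhere truth is discrete; PLP comparisons use `1e-12`.

## Known limitations

* The extension semantics of published repeat scanners are often
  underdocumented; our inclusion-maximal definition is principled and
  pinned by an oracle, but counts on real proteomes may differ slightly
  from numbers produced with other detectors.
* Conservation chaining across more than two species is anchored, not a
  full multiple-alignment consistency analysis; a repeat present in two
  non-anchor species at positions that overlap each other but not the
  anchor's cluster representative would be counted as two clusters.
* GO matching is keyword-on-name only — no ontology graph traversal or
  ancestor closure.
* The pipeline never runs BLAST or PRANK; it consumes their standard
  output formats and validates what it can.
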