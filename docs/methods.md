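# Methods

## Scope and model

The package implements the desk-scale computational counterpart of a
base-editor engineering workflow with three measurement arms:

1. a **transposon insertion screen** locating nCas9 positions tolerant of
   deaminase insertion, read out by mapping cargo-insertion breakpoints on a
   circular screening plasmid;
2. **amplicon deep-sequencing quantification** of on-target base editing and
   indels;
3. **off-target measurement**: RNA edit filtering from transcriptome
   pileups, genome-wide DNA SNV consensus from paired embryo samples
   (GOTI design), and guide-dependent off-target site prediction.

All coordinates are 0-based half-open internally; amino acids and VCF
positions are reported 1-based; protospacer positions run 1–20 with 1 at the
PAM-distal end.

## The screening plasmid and codon logic

The selection marker is an AmpR-like CDS whose codon 118 was CAA (Gln)
before a C>T change made it a TAA stop. Adenine editing acts A>G on the
bottom strand, which is T>C on the top strand, restoring CAA; the
`refmodel.predict_edit_consequence` round trip (TAA ↔ CAA) encodes exactly
this. We keep the field's "A118X" label for the mutation while following
the codon logic (the repaired residue is Gln); the naming tension is
inherited from the source material and has no computational consequence.

The nCas9-like CDS length parameter counts codons including the final stop;
residue indices therefore run 1..(len/3) and the last slot is the stop
codon. Features never overlap; features spanning the circular origin use
modulo arithmetic on a virtually doubled sequence, and all reported
positions are normalized to [0, plasmid length).

## Synthetic-data generator

Every generator is a pure function of (parameters, seed); a
`SyntheticTruth` record sufficient to score the downstream stage is always
emitted. Defaults, chosen once as the emulated study conditions:

* **TSD length 5 bp** — MuA transposition biology; the canonical insertion
  coordinate is the leftmost duplicated base.
* **Uniform insertion positions** over the plasmid (the screen's
  transposition step is efficient and unbiased); an optional per-position
  weight vector models hotspot bias.
* **Read model**: 150-nt reads, substitution errors only, two-state quality
  (Q37 correct / Q14 error). Two states are exactly what is needed to
  exercise the base-quality ≥ 30 filter; no PCR duplicates, no quality
  recalibration realism, no long reads.
* **Selection**: an insertion survives with probability `tolerance[residue]`
  iff it lies in the nCas9-like CDS and is in frame (offset and cargo length
  both ≡ 0 mod 3); colonies are drawn with replacement. The tolerance map
  stands in for the unknown per-site insertion tolerance of nCas9.
* **Caller emulation**: three callers at sensitivity 0.9 each, false
  positives Poisson(2·10⁻⁶ per bp), 50 germline-like variants shared across
  callers and samples. True CBE-induced SNVs carry a 92% C:G>T:A signature
  (cytosine-deamination chemistry); the non-signature remainder is drawn
  uniformly from the other ten substitution pairs so the signature fraction
  is exact in expectation.

What the generator does **not** emulate — alignment artifacts, mapping
bias, copy-number structure, caller-specific error models, strand bias —
bounds what passing tests show: they validate the pipeline's logic and
statistics, not robustness to real sequencing pathology.

## Insertion mapping

The backbone mapper is an exact k-mer (default 21) seed-and-extend over the
doubled circular backbone: the longest ungapped exact extension of the best
seed becomes the M block (minimum 30 nt), the unmatched read ends become
soft clips. Ambiguous best seeds (length ties at distinct loci) are flagged
mapq 0 and ignored downstream; reads mapping entirely to cargo carry no
junction information and are ignored. The mapper is deliberately minimal —
ungapped, exact — which is adequate for synthetic junction reads and keeps
the breakpoint arithmetic transparent.

Breakpoint calling matches a clip's junction-proximal 15 nt (default)
against the cargo termini in both orientations. **Junction micro-homology**
— the cargo terminus sharing bases with the adjacent backbone — lets the
exact extension absorb up to a few cargo bases into the M block (one base
with probability ~1/4, geometrically fewer beyond); the cargo match is
therefore retried at junction offsets up to 10 (smallest offset wins) and
the anchor corrected. Without this, roughly one junction read in four would
silently lose its call. Left- and right-junction anchors differ by the TSD
length and are normalized to the canonical leftmost-TSD-base coordinate
before merging; a clip matching both cargo ends (palindromic cargo) is
counted with orientation "ambiguous".

Per-position counts in the landscape summary count *calls*, not supporting
reads, so the per-feature totals partition the calls among disjoint
features plus "intergenic".

## Editing quantification

Pair merging scans ungapped overlaps ≥ 11 bp and picks the one maximizing
matches − mismatches, requiring ≤ 15% mismatches; with no acceptable
overlap both mates are kept. Amplicon alignment is gapped (edlib, infix
mode, ≤ 20% divergence). Pileups emit a column for every region position;
zero-depth columns report a *missing* rate, never 0, so window averages are
not deflated. Minus-strand sites are walked 3′→5′ with complemented bases,
making the profile invariant to the annotated strand. Indel ops count
read-level, irrespective of base quality (the mapping-quality filter still
applies); an insertion op counts when its insertion point falls within the
closed protospacer span, which absorbs the one-base representation
ambiguity of left-aligned indels.

Per-position rates (not per-read haplotypes) are the unit of reporting;
co-occurrence phasing is out of scope.

## Off-target analysis

* RNA filter: thresholds depth ≥ 10 and control reference fraction ≥ 0.99;
  the substitution is re-expressed on the gene's annotated strand before
  the A>G / C>T test.
* GOTI consensus: identity is (chrom, pos, ref, alt); per-caller metadata is
  ignored when intersecting. Consensus = ∩ of all caller sets minus the
  control set. Class summary collapses the 12 substitutions to 6
  strand-symmetric classes; an empty consensus yields a missing (None)
  proportion rather than 0.
* Scanner: windows of 23 nt on both strands; PAM pattern NRG = N, A/G, G at
  window positions 21–23. The seed region is the PAM-proximal 12 protospacer
  bases — a documented default, as tools differ and no single value is
  canonical. `total_mm` mode bounds total protospacer mismatches (≤ 3);
  `seed_aware` bounds seed (≤ 2) and non-seed (≤ 3) mismatches separately,
  so neither mode's result set is a subset of the other's by construction.
  The implementation is vectorized (numpy sliding windows); tests compare it
  against an independent naive per-window enumeration.

`fold_reduction` returns the raw ratio and its half-up rounding; a zero
denominator returns an infinite-reduction sentinel rather than raising,
since a test editor with no residual SNVs is a legitimate outcome.

## Problem sizes and numerical choices

Simulated problem sizes are chosen so that each statistical check has
adequate power at desk scale: 10,000 reads for rate recovery (3 binomial SD
bands), 20 seeds × 100 SNVs for the consensus-recall check against
sensitivity³, 200 insertion events for exact-recovery checks, and a
12,000-event library for the residue-coverage summary of the acceptance
script — at which the expected per-residue hit rate (~5.3 events per codon
within the CDS) saturates ~99% of residues, the same regime the screen
operates in at full scale. Statistical assertions use 3-SD tolerances
throughout; exact assertions (set equality against oracles, truth-table
boundaries) are used wherever the quantity is deterministic.

## Known limitations

* The backbone mapper is ungapped and exact; reads with indels or dense
  errors near a junction may lose their clip. Real libraries would be
  mapped with a production aligner and fed in as SAM (supported input).
* Insertion support counts junction reads, not deduplicated molecules;
  both granularities of the original screen (colony-level vs deep-seq
  breakpoints) can be emulated but the package does not pick one.
* RNA candidates overlapping genes on both strands are the caller's
  responsibility to annotate; the filter trusts the provided gene strand.
* Per-embryo aggregation of GOTI statistics (averaging before vs after
  class proportions) is left to the caller; the package reports per-sample.
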