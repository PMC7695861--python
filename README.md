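# bepipe

A Python library for the computational analyses behind engineering
high-specificity CRISPR base editors by embedding the deaminase inside
nCas9: mapping transposon insertion sites from soft-clipped reads,
quantifying on-target base editing from amplicon deep sequencing, and
measuring gRNA-dependent and gRNA-independent off-target editing on DNA and
RNA. A seeded synthetic-data generator replaces raw sequencing data and
records ground truth for every stage, so every analysis is scorable end to
end.

## Who it is for

Researchers analysing base-editor experiments at toy-to-desk scale:
transposon-based insertion screens on a plasmid backbone, amplicon
deep-sequencing editing assays, RNA-seq off-target profiling, and
GOTI-style (genome-wide off-target analysis by two-cell embryo injection)
whole-genome SNV comparisons.

## What it computes

**Insertion-site mapping** (`bepipe.insmap`). Library reads are mapped to
the circular plasmid with an exact k-mer seed-and-extend mapper (default
k = 21, minimum anchor 30 nt). A read spanning a backbone|cargo junction
aligns with a terminal soft clip; a clip of ≥ 20 nt whose junction-proximal
15 nt match a cargo terminus calls a breakpoint. The two junction anchors of
one insertion differ by the 5-bp target-site duplication (TSD) left by MuA
transposition; both are normalized to the leftmost duplicated base and
merged. Summaries report per-position, per-feature, and per-residue counts,
including the fraction of nCas9 residues hit.

**Editing quantification** (`bepipe.editquant`). Read pairs merge on an
ungapped overlap ≥ 11 bp (disagreements resolved to the higher-quality base,
consensus quality max − min). Pileups count bases with mapping quality ≥ 20
and base quality ≥ 30. The conversion rate at protospacer position *i* (1 =
PAM-distal) is N(edited)/depth, strand-aware; the indel frequency is the
fraction of mapped reads with ≥ 1 inserted or deleted base in the
protospacer.

**Off-target analysis** (`bepipe.offtarget`). RNA candidates pass only with
depth ≥ 10, ≥ 99% reference reads in wild-type samples, and the editor's
chemistry (A>G for ABE, C>T for CBE) on the transcribed strand. DNA
consensus is S₁ ∩ S₂ ∩ S₃ of three caller sets minus the paired uninjected
control, keyed on (chrom, pos, ref, alt); substitution classes collapse to
six strand-symmetric categories with the C:G>T:A proportion reported.
Guide-dependent sites are 23-nt windows with an NRG/NGG PAM and protospacer
mismatches ≤ 3 total, or ≤ 2 in the 12-nt PAM-proximal seed and ≤ 3
elsewhere.

**Codon consequences** (`bepipe.refmodel`). The selection readout of the
insertion screen: a TAA stop repaired by top-strand T>C (A>G on the bottom
strand) becomes CAA (Gln); the reverse C>T creates the premature stop.

**Synthetic data** (`bepipe.simkit`). Pure functions of (parameters, seed)
generating the screening plasmid, insertion libraries, selection, shotgun
and amplicon reads (Q37/Q14 two-state qualities), and three-caller SNV
output sets — each with a JSON-serializable ground-truth record.

## Worked example

`python examples/02_amplicon_editing.py` simulates 5,000 amplicon reads with
known A>G conversion rates at protospacer positions 3, 5, and 8 plus a 3%
1-bp indel rate, then quantifies them:

```
position  truth  estimated
  A3      0.10   0.103
  A5      0.86   0.852
  A8      0.30   0.300
indel frequency: 0.0334  (truth 0.03)
```

Each estimate is the filtered-pileup conversion rate at that protospacer
position; agreement with truth is within binomial sampling error at this
read depth. The other examples (`examples/01...05`) walk the insertion
screen, the RNA filter, the GOTI consensus, and the off-target scanner the
same way.

A thin CLI wraps the same functions for shell use
(`bepipe simulate-library`, `map-insertions`, `quantify-editing`,
`filter-rna-edits`, `goti-consensus`, `predict-offtargets`, `report`); runs
with the same seed are byte-identical.

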