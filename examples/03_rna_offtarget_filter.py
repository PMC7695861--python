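"""RNA off-target filtering: depth, wild-type reference fraction, and
transcribed-strand chemistry rules.

Candidates are kept only when covered at >=10x, clean in the wild-type
samples (>=99% reference reads), and carrying the editor's chemistry on the
transcribed strand - A>G for an adenine editor, meaning a T>C call on a
minus-strand gene also qualifies.
"""
from bepipe.offtarget import RnaEditCandidate, filter_rna_edits, fold_reduction

candidates = [
    RnaEditCandidate("chr1", 101, "A", "G", depth=45, alt_count=9,
                     gene_strand="+", control_ref_fraction=1.00),   # kept
    RnaEditCandidate("chr1", 202, "A", "G", depth=9, alt_count=3,
                     gene_strand="+", control_ref_fraction=1.00),   # depth < 10
    RnaEditCandidate("chr2", 303, "A", "G", depth=60, alt_count=12,
                     gene_strand="+", control_ref_fraction=0.985),  # dirty WT
    RnaEditCandidate("chr2", 404, "T", "C", depth=80, alt_count=20,
                     gene_strand="-", control_ref_fraction=1.00),   # A>G on gene
    RnaEditCandidate("chr3", 505, "C", "T", depth=70, alt_count=15,
                     gene_strand="+", control_ref_fraction=1.00),   # CBE not ABE
]
kept = filter_rna_edits(candidates, mode="ABE")
print(f"kept {len(kept)} of {len(candidates)} candidates:")
for c in kept:
    print(f"  {c.chrom}:{c.pos} {c.ref}>{c.alt} (gene strand {c.gene_strand})")

fc = fold_reduction(20739, 88)
print(f"\ntranscriptome SNV fold reduction 20739 -> 88: "
      f"{fc.ratio:.2f} (~{fc.rounded:.0f}x)")
# Two candidates survive: the plus-strand A>G and the minus-strand T>C
# (which is A>G on the transcribed strand).  The fold-change arithmetic shows
# how a ~236x reduction in transcriptome-wide SNVs is computed from counts.
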