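"""Off-target analysis: RNA edit filtering, multi-caller SNV consensus,
substitution-class summaries, fold-change arithmetic, and guide-dependent
off-target site prediction.

The DNA off-target logic follows the GOTI design: an edited and an uninjected
sister blastomere are sequenced, three independent callers report de novo
SNVs in the edited sample, and the intersection of the three call sets minus
the control defines the true variant set.  RNA off-target candidates are
filtered on depth, on the wild-type reference-allele fraction, and on the
substitution expressed on the transcribed strand.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from bepipe.refmodel import TargetSite, complement, reverse_complement

__all__ = [
    "VariantRecord",
    "RnaEditCandidate",
    "ConsensusSet",
    "SnvClassSummary",
    "FoldChange",
    "OffTargetHit",
    "filter_rna_edits",
    "goti_consensus",
    "classify_snvs",
    "fold_reduction",
    "predict_guide_dependent_sites",
    "SNV_CLASSES",
]


@dataclass(frozen=True)
class VariantRecord:
    """One SNV attributable to a sample and caller.

    Identity for consensus purposes is ``(chrom, pos, ref, alt)`` only —
    callers report differing depth/metadata for the same event.  ``pos`` is
    1-based (VCF convention).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int = 0
    alt_count: int = 0
    sample: str = ""
    caller: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.alt_count > self.depth:
            raise ValueError("alt_count exceeds depth")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class RnaEditCandidate:
    """A candidate RNA edit with the annotations the filter needs."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_count: int
    gene_strand: str  # strand of the transcribed gene
    control_ref_fraction: float  # reference-allele fraction in wild-type samples
    sample: str = ""

    def __post_init__(self) -> None:
        if self.gene_strand not in {"+", "-"}:
            raise ValueError("gene_strand must be + or -")
        if not 0.0 <= self.control_ref_fraction <= 1.0:
            raise ValueError("control_ref_fraction must be in [0,1]")


@dataclass(frozen=True)
class ConsensusSet:
    """Intersection of the three caller sets minus the paired control."""

    variants: frozenset
    per_caller_sizes: tuple[int, ...]
    n_before_control: int

    @property
    def count(self) -> int:
        return len(self.variants)


SNV_CLASSES = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C",
    "T:A>C:G", "T:A>A:T", "T:A>G:C",
)

_CLASS_OF = {
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
    ("T", "C"): "T:A>C:G", ("A", "G"): "T:A>C:G",
    ("T", "A"): "T:A>A:T", ("A", "T"): "T:A>A:T",
    ("T", "G"): "T:A>G:C", ("A", "C"): "T:A>G:C",
}


@dataclass(frozen=True)
class SnvClassSummary:
    """Strand-symmetric substitution-class counts (12 classes collapsed to 6)."""

    counts: dict
    total: int
    proportion_CG_to_TA: Optional[float]


@dataclass(frozen=True)
class FoldChange:
    """A ratio of SNV counts, raw and rounded to the nearest integer.

    A zero denominator yields an infinite-reduction sentinel rather than an
    exception: a test editor with no residual off-targets is a valid outcome.
    """

    ratio: float
    rounded: float  # int-valued, or math.inf

    @property
    def infinite(self) -> bool:
        return math.isinf(self.ratio)


# -------------------------------------------------------------- RNA filtering

def filter_rna_edits(
    candidates: Iterable[RnaEditCandidate],
    mode: str,
    min_depth: int = 10,
    min_control_ref_fraction: float = 0.99,
) -> list[RnaEditCandidate]:
    """Keep candidate RNA edits that look like true deaminase products.

    A candidate passes iff (i) its depth is at least ``min_depth``, (ii) the
    wild-type samples support the reference allele at a fraction of at least
    ``min_control_ref_fraction``, and (iii) the substitution, re-expressed on
    the transcribed (gene) strand, is A>G for ABE mode or C>T for CBE mode.
    A T>C call on a minus-strand gene is therefore an A>G edit and is kept in
    ABE mode.
    """
    if mode not in {"ABE", "CBE"}:
        raise ValueError(f"unknown editor mode {mode!r}; expected 'ABE' or 'CBE'")
    want = ("A", "G") if mode == "ABE" else ("C", "T")
    kept = []
    for c in candidates:
        if c.depth < min_depth:
            continue
        if c.control_ref_fraction < min_control_ref_fraction:
            continue
        ref, alt = c.ref, c.alt
        if c.gene_strand == "-":
            ref, alt = complement(ref), complement(alt)
        if (ref, alt) == want:
            kept.append(c)
    return kept


# ------------------------------------------------------------- GOTI consensus

def goti_consensus(
    caller_sets: Sequence[Iterable[VariantRecord]],
    control_set: Iterable[VariantRecord] = (),
) -> ConsensusSet:
    """SNVs reported by every caller, minus the paired-control variants.

    Matching is on the ``(chrom, pos, ref, alt)`` identity key; depth and
    other per-caller metadata are ignored.
    """
    key_sets = [frozenset(v.key for v in s) for s in caller_sets]
    if not key_sets:
        raise ValueError("at least one caller set is required")
    inter = frozenset.intersection(*key_sets)
    control_keys = frozenset(v.key for v in control_set)
    final = inter - control_keys
    return ConsensusSet(
        variants=final,
        per_caller_sizes=tuple(len(s) for s in key_sets),
        n_before_control=len(inter),
    )


def classify_snvs(variants: Iterable) -> SnvClassSummary:
    """Collapse SNVs into the six strand-symmetric substitution classes.

    ``proportion_CG_to_TA`` is the fraction of C>T plus G>A events — the
    signature of cytosine deamination.  An empty input yields a missing
    proportion (quantification is not meaningful on a handful of SNVs, let
    alone zero).
    """
    counts = {c: 0 for c in SNV_CLASSES}
    total = 0
    for v in variants:
        ref, alt = (v.ref, v.alt) if hasattr(v, "ref") else (v[2], v[3])
        cls = _CLASS_OF.get((ref, alt))
        if cls is None:
            raise ValueError(f"not a SNV substitution: {ref}>{alt}")
        counts[cls] += 1
        total += 1
    prop = counts["C:G>T:A"] / total if total else None
    return SnvClassSummary(counts=counts, total=total, proportion_CG_to_TA=prop)


def fold_reduction(n_reference_editor: int, n_test_editor: int) -> FoldChange:
    """Fold change in SNV count between a reference and a test editor."""
    if n_reference_editor < 0 or n_test_editor < 0:
        raise ValueError("counts must be non-negative")
    if n_test_editor == 0:
        return FoldChange(ratio=math.inf, rounded=math.inf)
    ratio = n_reference_editor / n_test_editor
    return FoldChange(ratio=ratio, rounded=float(int(ratio + 0.5)))


# ---------------------------------------------------- guide-dependent scanner

@dataclass(frozen=True)
class OffTargetHit:
    chrom: str
    position: int  # 0-based leftmost genomic coordinate of the 23-nt window
    strand: str
    mismatches: int


_ENC = {"A": 65, "C": 67, "G": 71, "T": 84}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _pam_mask(win: np.ndarray, pam: str) -> np.ndarray:
    # window columns 20..22 hold the PAM; N matches anything, R matches A/G
    p2, p3 = win[:, 21], win[:, 22]
    if pam == "NGG":
        return (p2 == _ENC["G"]) & (p3 == _ENC["G"])
    if pam == "NRG":
        return ((p2 == _ENC["A"]) | (p2 == _ENC["G"])) & (p3 == _ENC["G"])
    raise ValueError(f"unsupported PAM pattern {pam!r}")


def _scan_strand(seq: str, proto: np.ndarray, pam: str, seed_len: int):
    """Per-window protospacer mismatch counts (total and seed) + PAM mask."""
    code = _encode(seq)
    if code.size < 23:
        return None
    win = sliding_window_view(code, 23)
    mm_matrix = win[:, :20] != proto
    total_mm = mm_matrix.sum(axis=1)
    seed_mm = mm_matrix[:, 20 - seed_len:].sum(axis=1)
    return total_mm, seed_mm, _pam_mask(win, pam)


def predict_guide_dependent_sites(
    genome: str | dict[str, str],
    site: TargetSite,
    mode: str = "seed_aware",
    max_mm: int = 3,
    seed_len: int = 12,
    seed_max_mm: int = 2,
    nonseed_max_mm: int = 3,
    pam: Optional[str] = None,
) -> list[OffTargetHit]:
    """Scan a genome for candidate gRNA-dependent off-target sites.

    Both strands are scanned for 23-nt windows whose last 3 nt match the PAM
    pattern.  ``total_mm`` mode keeps windows with at most ``max_mm``
    protospacer mismatches; ``seed_aware`` mode bounds mismatches separately
    in the PAM-proximal seed (last ``seed_len`` protospacer bases, at most
    ``seed_max_mm``) and in the remainder (at most ``nonseed_max_mm``).

    The reported position is the 0-based leftmost genomic coordinate of the
    23-nt window on the forward sequence, with ``strand`` saying which strand
    carries the protospacer.
    """
    if mode not in {"total_mm", "seed_aware"}:
        raise ValueError(f"unknown scan mode {mode!r}")
    if not 1 <= seed_len <= 20:
        raise ValueError("seed_len must be in 1..20")
    pam_pat = pam if pam is not None else site.pam
    contigs = {"genome": genome} if isinstance(genome, str) else genome
    proto = _encode(site.protospacer)

    hits: list[OffTargetHit] = []
    for chrom, seq in contigs.items():
        seq = seq.upper()
        n = len(seq)
        for strand, scan_seq in (("+", seq), ("-", reverse_complement(seq))):
            res = _scan_strand(scan_seq, proto, pam_pat, seed_len)
            if res is None:
                continue
            total_mm, seed_mm, pam_ok = res
            if mode == "total_mm":
                keep = pam_ok & (total_mm <= max_mm)
            else:
                nonseed_mm = total_mm - seed_mm
                keep = pam_ok & (seed_mm <= seed_max_mm) & (nonseed_mm <= nonseed_max_mm)
            for j in np.flatnonzero(keep):
                pos = int(j) if strand == "+" else n - 23 - int(j)
                hits.append(OffTargetHit(chrom, pos, strand, int(total_mm[j])))
    hits.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return hits
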