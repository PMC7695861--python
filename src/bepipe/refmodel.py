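"""Coordinate frame, circular plasmid model, and codon-consequence logic.

Everything downstream (insertion mapping, editing quantification, off-target
scanning) shares the conventions defined here:

* nucleotide coordinates are 0-based, half-open, and taken modulo the plasmid
  length on circular references;
* amino-acid positions are reported 1-based (``1048Thr`` style);
* protospacer positions are numbered 1–20 with position 1 at the PAM-distal
  (5') end and position 20 abutting the PAM.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

__all__ = [
    "CircularSequence",
    "GeneFeature",
    "PlasmidMap",
    "TargetSite",
    "complement",
    "reverse_complement",
    "translate",
    "aa_position_of",
    "predict_edit_consequence",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
STOP_CODONS = {"TAA", "TAG", "TGA"}


def complement(seq: str) -> str:
    """Base-wise complement (same orientation)."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_dna(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)!r}")


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Returns one letter per codon, ``*`` for stop codons.  The input must be
    an in-frame {A,C,G,T} string (length a multiple of 3); anything else is
    rejected rather than silently truncated.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    _check_dna(cds, "CDS")
    if not cds:
        return ""
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class CircularSequence:
    """A circular DNA sequence; indexing and slicing wrap modulo the length."""

    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("circular sequence must be non-empty")
        _check_dna(self.seq, "plasmid sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, i: int) -> str:
        return self.seq[i % len(self.seq)]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with circular wrap-around; the span may
        cross the origin (virtual doubled sequence)."""
        n = len(self.seq)
        span = end - start
        if span < 0:
            raise ValueError("fetch requires end >= start")
        if span > 2 * n:
            raise ValueError("fetch span exceeds twice the plasmid length")
        start %= n
        doubled = self.seq + self.seq
        return doubled[start:start + span]

    def reverse_complement(self) -> "CircularSequence":
        return CircularSequence(reverse_complement(self.seq))


@dataclass(frozen=True)
class GeneFeature:
    """An annotated interval on the plasmid.

    ``[start, end)`` is 0-based; a feature spanning the circular origin is
    represented with ``end > plasmid length`` (modulo semantics).
    """

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "other"  # CDS | marker | origin | other

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"feature {self.name}: invalid interval [{self.start},{self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name}: strand must be + or -")
        if self.kind == "CDS" and (self.end - self.start) % 3 != 0:
            raise ValueError(f"CDS feature {self.name}: length not a multiple of 3")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int, ref_len: int) -> bool:
        """Interval membership under circular coordinates."""
        p = pos % ref_len
        return self.start <= p < self.end or self.start <= p + ref_len < self.end

    def offset_of(self, pos: int, ref_len: int) -> Optional[int]:
        """Nucleotide offset of ``pos`` from the CDS start, in translation
        orientation; None if outside the feature."""
        if not self.contains(pos, ref_len):
            return None
        p = pos % ref_len
        if p < self.start:
            p += ref_len
        if self.strand == "+":
            return p - self.start
        return (self.end - 1) - p


@dataclass(frozen=True)
class PlasmidMap:
    """Circular reference plus typed features; the coordinate frame for the
    insertion screen."""

    sequence: CircularSequence
    features: tuple[GeneFeature, ...]
    premature_stop: Optional[tuple[str, int]] = None  # (feature name, 1-based codon)

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique")
        n = len(self.sequence)
        for f in self.features:
            if f.end > 2 * n:
                raise ValueError(f"feature {f.name} exceeds doubled plasmid length")
        if self.premature_stop is not None:
            fname, codon_idx = self.premature_stop
            codon = self.codon(fname, codon_idx)
            if translate(codon) != "*":
                raise ValueError(
                    f"premature_stop codon {codon_idx} of {fname} is {codon!r}, not a stop"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def feature_sequence(self, name: str) -> str:
        f = self.feature(name)
        raw = self.sequence.fetch(f.start, f.end)
        return reverse_complement(raw) if f.strand == "-" else raw

    def codon(self, feature_name: str, codon_index: int) -> str:
        """1-based codon of a CDS feature, in translation orientation."""
        cds = self.feature_sequence(feature_name)
        i = (codon_index - 1) * 3
        if i < 0 or i + 3 > len(cds):
            raise IndexError(f"codon {codon_index} outside {feature_name}")
        return cds[i:i + 3]


@dataclass(frozen=True)
class TargetSite:
    """A 20-nt protospacer plus PAM on a named reference.

    ``position`` is the 0-based leftmost reference coordinate of the
    protospacer; protospacer position 1 is the PAM-distal base.
    """

    protospacer: str
    pam: str
    ref_name: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be exactly 20 nt")
        _check_dna(self.protospacer, "protospacer")
        if self.pam not in {"NGG", "NRG"}:
            raise ValueError("PAM pattern must be NGG or NRG")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be + or -")

    def ref_index(self, proto_pos: int) -> int:
        """Reference coordinate of protospacer position ``proto_pos`` (1–20)."""
        if not 1 <= proto_pos <= 20:
            raise ValueError("protospacer position must be in 1..20")
        if self.strand == "+":
            return self.position + proto_pos - 1
        return self.position + 20 - proto_pos


def aa_position_of(breakpoint: int, cds: GeneFeature, ref_len: int) -> Optional[int]:
    """1-based amino-acid index of a nucleotide breakpoint within a CDS.

    Returns ``floor(offset/3) + 1`` where ``offset`` is the nucleotide offset
    from the CDS start in translation orientation, or None when the
    breakpoint lies outside the CDS (not an error: most insertions land in
    backbone or marker sequence).
    """
    off = cds.offset_of(breakpoint, ref_len)
    if off is None:
        return None
    return off // 3 + 1


def _parse_change(edit: str | tuple[str, str]) -> tuple[str, str]:
    if isinstance(edit, tuple):
        ref, alt = edit
    else:
        ref, _, alt = edit.partition(">")
    ref, alt = ref.strip().upper(), alt.strip().upper()
    if ref not in _DNA or alt not in _DNA or ref == alt:
        raise ValueError(f"invalid base change {edit!r}")
    return ref, alt


def predict_edit_consequence(
    codon: str, codon_position: int, edit: str | tuple[str, str]
) -> tuple[str, str]:
    """Apply a top-strand single-base change to a codon and translate.

    ``edit`` is written on the top (coding) strand, e.g. ``"T>C"``; an A>G
    deamination on the bottom strand is expressed by the caller as the
    equivalent top-strand T>C.  A position outside 1–3 leaves the codon
    unchanged (the edit falls in a neighbouring codon).

    Returns ``(edited codon, residue)`` — e.g. a TAA stop with T>C at
    position 1 becomes CAA encoding Q, which is the selection readout of the
    insertion screen.
    """
    if len(codon) != 3:
        raise ValueError("codon must be 3 nt")
    _check_dna(codon, "codon")
    if codon_position < 1 or codon_position > 3:
        return codon, translate(codon)
    ref, alt = _parse_change(edit)
    if codon[codon_position - 1] != ref:
        raise ValueError(
            f"codon {codon} has {codon[codon_position - 1]} at position "
            f"{codon_position}, not {ref}"
        )
    new = codon[: codon_position - 1] + alt + codon[codon_position:]
    return new, translate(new)
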