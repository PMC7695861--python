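"""Insertion-site mapping from soft-clipped reads.

Reads from the insertion library are mapped to the circular plasmid backbone
with a minimal exact k-mer seed-and-extend mapper (ungapped — adequate for
junction reads from synthetic libraries).  A read spanning a cargo junction
aligns with one terminal soft clip; the clipped segment is matched against
the cargo termini and the clip anchor, corrected for the target-site
duplication, gives the canonical insertion coordinate (leftmost duplicated
base).  Calls are merged across the two junction sides of an event and
summarized into a per-position / per-feature / per-residue insertion
landscape.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from bepipe.io import Read
from bepipe.refmodel import (
    CircularSequence,
    GeneFeature,
    PlasmidMap,
    aa_position_of,
    reverse_complement,
)

__all__ = [
    "AlignedRead",
    "SoftClipSegment",
    "InsertionCall",
    "InsertionProfile",
    "BackboneIndex",
    "align_to_backbone",
    "extract_softclips",
    "call_breakpoints",
    "summarize_profile",
]


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped-or-simple alignment in SAM-like convention: for '-' strand
    alignments ``query`` holds the reverse-complemented read and the CIGAR
    refers to that stored sequence."""

    name: str
    query: str
    ref_start: int
    cigar: tuple  # ordered ( (op, length), ... ), op in {M,I,D,S}
    mapq: int
    strand: str = "+"
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "cigar", tuple(self.cigar))
        qlen = sum(l for op, l in self.cigar if op in "MIS")
        if qlen != len(self.query):
            raise ValueError(
                f"{self.name}: CIGAR consumes {qlen} query bases, read has {len(self.query)}"
            )

    @property
    def reference_span(self) -> int:
        return sum(l for op, l in self.cigar if op in "MD")

    def quals_or_default(self, default: int = 37) -> list[int]:
        """Numeric base qualities; a missing quality string counts as high
        quality (synthetic error-free input)."""
        if self.qual is None:
            return [default] * len(self.query)
        return [ord(c) - 33 for c in self.qual]


@dataclass(frozen=True)
class SoftClipSegment:
    """A terminal soft-clipped segment and the backbone position it abuts."""

    read_id: str
    side: str  # 'left' or 'right'
    seq: str
    anchor: int  # 0-based backbone position of the clip boundary


@dataclass(frozen=True)
class InsertionCall:
    """A cargo insertion breakpoint, canonicalized to the leftmost
    duplicated (TSD) base."""

    position: int
    support: int
    orientations: frozenset
    junction_sides: frozenset
    aa_position: Optional[int] = None
    in_frame: bool = False


@dataclass
class InsertionProfile:
    """The insertion landscape over the plasmid."""

    position_counts: np.ndarray  # one slot per plasmid position
    feature_totals: dict  # feature name (+ 'intergenic') -> call count
    aa_counts: dict  # amino-acid index -> call count, designated CDS
    fraction_aa_covered: float
    n_calls: int


# --------------------------------------------------------------------- mapper

class BackboneIndex:
    """Exact k-mer index of the doubled circular backbone."""

    def __init__(self, backbone: str | CircularSequence | PlasmidMap, k: int = 21):
        if isinstance(backbone, PlasmidMap):
            backbone = backbone.sequence
        if isinstance(backbone, CircularSequence):
            backbone = backbone.seq
        if k < 8:
            raise ValueError("seed length k must be >= 8")
        self.seq = backbone
        self.length = len(backbone)
        self.k = k
        self.doubled = backbone + backbone
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(self.length):
            index[self.doubled[i:i + k]].append(i)
        self.index = dict(index)


def _extend(doubled: str, read: str, q: int, r: int, k: int) -> tuple[int, int, int]:
    """Maximal ungapped exact extension of a seed (read[q:q+k] == doubled[r:r+k]).

    Returns (query_start, query_end, ref_start_in_doubled) of the match block.
    """
    qs, rs = q, r
    while qs > 0 and rs > 0 and read[qs - 1] == doubled[rs - 1]:
        qs -= 1
        rs -= 1
    qe, re_ = q + k, r + k
    n = len(doubled)
    while qe < len(read) and re_ < n and read[qe] == doubled[re_]:
        qe += 1
        re_ += 1
    return qs, qe, rs


def align_to_backbone(
    read: Read | str,
    backbone: BackboneIndex | str | CircularSequence | PlasmidMap,
    k: int = 21,
    min_anchor: int = 30,
) -> Optional[AlignedRead]:
    """Map a read to the circular backbone by exact seed-and-extend.

    The longest ungapped exact extension of the best seed becomes the M
    block; the unmatched prefix/suffix become soft clips.  Circularity is
    handled by seeding against a doubled backbone and normalizing positions
    modulo the length.  Returns None when no seed hits or the best match is
    shorter than ``min_anchor``; a length tie between distinct loci returns
    an alignment flagged ambiguous with ``mapq=0``.
    """
    if not isinstance(backbone, BackboneIndex):
        backbone = BackboneIndex(backbone, k=k)
    idx, L, doubled = backbone.index, backbone.length, backbone.doubled
    k = backbone.k
    name = read.name if isinstance(read, Read) else "read"
    qual = read.qual if isinstance(read, Read) else None
    seq = (read.seq if isinstance(read, Read) else read).upper()
    if len(seq) < k:
        return None

    best = None  # (mlen, qs, qe, rs, strand, oriented_seq, oriented_qual)
    ambiguous = False
    for strand, s, q in (
        ("+", seq, qual),
        ("-", reverse_complement(seq), qual[::-1] if qual else None),
    ):
        seen_diag: set[tuple[int, int]] = set()
        j = 0
        while j <= len(s) - k:
            hits = idx.get(s[j:j + k])
            if hits:
                for r in hits:
                    diag = ((r - j) % L, 0 if strand == "+" else 1)
                    if diag in seen_diag:
                        continue
                    seen_diag.add(diag)
                    # lift hits near the origin into the second copy of the
                    # doubled backbone so left extension can wrap
                    r_eff = r + L if r < j else r
                    qs, qe, rs = _extend(doubled, s, j, r_eff, k)
                    mlen = qe - qs
                    if best is None or mlen > best[0]:
                        best = (mlen, qs, qe, rs, strand, s, q)
                        ambiguous = False
                    elif mlen == best[0]:
                        same = (
                            strand == best[4]
                            and (rs - qs) % L == (best[3] - best[1]) % L
                        )
                        if not same:
                            ambiguous = True
            j += 1

    if best is None:
        return None
    mlen, qs, qe, rs, strand, s, q = best
    if mlen < min_anchor:
        return None
    cigar = []
    if qs > 0:
        cigar.append(("S", qs))
    cigar.append(("M", mlen))
    if qe < len(s):
        cigar.append(("S", len(s) - qe))
    return AlignedRead(
        name=name,
        query=s,
        ref_start=rs % L,
        cigar=tuple(cigar),
        mapq=0 if ambiguous else 60,
        strand=strand,
        qual=q,
    )


# ----------------------------------------------------------------- soft clips

def extract_softclips(
    aligned: AlignedRead,
    min_clip_len: int = 20,
    backbone_len: Optional[int] = None,
) -> list[SoftClipSegment]:
    """Terminal soft-clipped segments of an alignment.

    A left clip anchors at ``ref_start``; a right clip at ``ref_start`` plus
    the reference span (modulo the backbone length if given).
    """
    if not aligned.cigar:
        raise ValueError("alignment has no CIGAR")
    segs: list[SoftClipSegment] = []
    first_op, first_len = aligned.cigar[0]
    if first_op == "S" and first_len >= min_clip_len:
        segs.append(SoftClipSegment(
            aligned.name, "left", aligned.query[:first_len], aligned.ref_start
        ))
    last_op, last_len = aligned.cigar[-1]
    if len(aligned.cigar) > 1 and last_op == "S" and last_len >= min_clip_len:
        anchor = aligned.ref_start + aligned.reference_span
        if backbone_len:
            anchor %= backbone_len
        segs.append(SoftClipSegment(
            aligned.name, "right", aligned.query[-last_len:], anchor
        ))
    return segs


# ---------------------------------------------------------------- breakpoints

def call_breakpoints(
    segments: Iterable[SoftClipSegment],
    cargo: str,
    plasmid: PlasmidMap | CircularSequence | str,
    tsd_len: int = 5,
    min_cargo_match: int = 15,
    cds: Optional[GeneFeature] = None,
    cargo_in_frame: bool = True,
    max_slip: int = 10,
) -> list[InsertionCall]:
    """Turn soft-clip segments into merged insertion calls.

    A segment supports an insertion iff its junction-proximal bases match a
    cargo terminus with at least ``min_cargo_match`` exact bases: a *right*
    clip (backbone then cargo) must begin with the cargo start, a *left* clip
    (cargo then backbone) must end with the cargo end — each in either
    orientation.  Micro-homology between the cargo terminus and the adjacent
    backbone lets the exact-match extension absorb up to a few cargo bases
    into the aligned block; the match is therefore retried at junction
    offsets up to ``max_slip`` and the anchor corrected accordingly (the
    smallest offset wins).  The two junction anchors of one event differ by
    ``tsd_len`` (the target-site duplication); both are normalized to the
    canonical leftmost-TSD-base coordinate and merged, summing support.
    """
    if len(cargo) < min_cargo_match:
        raise ValueError("cargo shorter than min_cargo_match")
    if isinstance(plasmid, (PlasmidMap, CircularSequence)):
        L = len(plasmid)
    else:
        L = len(plasmid)
    m = min_cargo_match
    cargo_rc = reverse_complement(cargo)

    def match_right(clip: str):
        """Clip follows the backbone: must begin with a cargo start, allowing
        k absorbed cargo bases.  Returns (orientations, anchor shift)."""
        for k in range(0, max_slip + 1):
            found = [o for o, c in (("+", cargo), ("-", cargo_rc))
                     if k + m <= len(c) and clip[:m] == c[k:k + m]]
            if found:
                return found, -k
        return [], 0

    def match_left(clip: str):
        """Clip precedes the backbone: must end with a cargo end, allowing
        k absorbed cargo bases."""
        for k in range(0, max_slip + 1):
            found = []
            for o, c in (("+", cargo), ("-", cargo_rc)):
                if k + m > len(c):
                    continue
                tail = c[-(m + k):len(c) - k] if k else c[-m:]
                if clip[-m:] == tail:
                    found.append(o)
            if found:
                return found, k
        return [], 0

    acc: dict[int, dict] = {}
    for seg in segments:
        if len(seg.seq) < m:
            continue
        if seg.side == "right":
            matches, shift = match_right(seg.seq)
            canonical = (seg.anchor + shift - tsd_len) % L
        else:
            matches, shift = match_left(seg.seq)
            canonical = (seg.anchor + shift) % L
        if not matches:
            continue
        orientation = matches[0] if len(matches) == 1 else "ambiguous"
        slot = acc.setdefault(canonical, {"support": 0, "orient": set(), "sides": set()})
        slot["support"] += 1
        slot["orient"].add(orientation)
        slot["sides"].add(seg.side)

    calls = []
    for pos in sorted(acc):
        slot = acc[pos]
        aa = aa_position_of(pos, cds, L) if cds is not None else None
        in_frame = False
        if cds is not None:
            off = cds.offset_of(pos, L)
            in_frame = off is not None and off % 3 == 0 and cargo_in_frame
        calls.append(InsertionCall(
            position=pos,
            support=slot["support"],
            orientations=frozenset(slot["orient"]),
            junction_sides=frozenset(slot["sides"]),
            aa_position=aa,
            in_frame=in_frame,
        ))
    return calls


# -------------------------------------------------------------------- summary

def summarize_profile(
    calls: Sequence[InsertionCall],
    plasmid: PlasmidMap,
    cds_name: str = "nCas9",
) -> InsertionProfile:
    """Per-position, per-feature and per-residue insertion landscape.

    ``fraction_aa_covered`` is the fraction of amino-acid positions of the
    designated CDS hit by at least one call.
    """
    L = len(plasmid)
    counts = np.zeros(L, dtype=int)
    feature_totals = {f.name: 0 for f in plasmid.features}
    feature_totals["intergenic"] = 0
    cds = plasmid.feature(cds_name)
    n_aa = len(cds) // 3
    aa_counts: dict[int, int] = {}
    for c in calls:
        counts[c.position % L] += 1
        hit = None
        for f in plasmid.features:
            if f.contains(c.position, L):
                hit = f.name
                break
        feature_totals[hit if hit else "intergenic"] += 1
        aa = aa_position_of(c.position, cds, L)
        if aa is not None:
            aa_counts[aa] = aa_counts.get(aa, 0) + 1
    frac = len(aa_counts) / n_aa if n_aa else 0.0
    return InsertionProfile(
        position_counts=counts,
        feature_totals=feature_totals,
        aa_counts=aa_counts,
        fraction_aa_covered=frac,
        n_calls=len(calls),
    )


def calls_to_dataframe(calls: Sequence[InsertionCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "position": c.position,
            "aa_position": c.aa_position if c.aa_position is not None else "",
            "support": c.support,
            "orientations": ",".join(sorted(c.orientations)),
            "junction_sides": ",".join(sorted(c.junction_sides)),
            "in_frame": int(c.in_frame),
        }
        for c in calls
    ], columns=["position", "aa_position", "support", "orientations",
                "junction_sides", "in_frame"])
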