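"""On-target editing quantification from amplicon deep-sequencing reads.

Read pairs are merged on an ungapped overlap of at least 11 bp, aligned to
the amplicon (gapped, via edlib), and piled up under mapping-quality >= 20
and base-quality >= 30 filters.  Per-protospacer-position conversion rates
(A>G for adenine editors, C>T for cytosine editors) are reported with
position 1 at the PAM-distal end regardless of which amplicon strand carries
the protospacer; indel frequency is the fraction of mapped reads carrying at
least one inserted or deleted base inside the protospacer.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from bepipe.insmap import AlignedRead
from bepipe.io import Read, qual_char
from bepipe.refmodel import TargetSite, complement, reverse_complement

__all__ = [
    "PileupColumn",
    "EditingProfile",
    "IndelStats",
    "merge_read_pairs",
    "align_to_amplicon",
    "build_pileup",
    "conversion_rate",
    "protospacer_profile",
    "indel_frequency",
    "window_summary",
]


@dataclass(frozen=True)
class PileupColumn:
    """Filtered base counts at one reference position."""

    ref_pos: int
    ref_base: str
    counts: dict  # base -> count, bases passing filters only

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class EditingProfile:
    """Per-protospacer-position conversion rates for one target site.

    Only positions whose protospacer base is the editable base appear; an
    editable position with zero filtered depth is listed in
    ``no_depth_positions`` rather than reported as rate 0.
    """

    site: TargetSite
    edit_type: str  # 'A>G' or 'C>T'
    rates: dict  # protospacer position (1-20) -> fraction
    depths: dict  # protospacer position -> filtered depth
    no_depth_positions: frozenset = frozenset()


@dataclass(frozen=True)
class IndelStats:
    indel_reads: int
    total_reads: int

    @property
    def frequency(self) -> float:
        return self.indel_reads / self.total_reads if self.total_reads else 0.0


# -------------------------------------------------------------- pair merging

def merge_read_pairs(
    r1: Read,
    r2: Read,
    min_overlap: int = 11,
    max_mismatch_frac: float = 0.15,
):
    """Combine a read pair into a single consensus read when the mates
    overlap by at least ``min_overlap`` ungapped bases.

    Mate 2 is reverse-complemented; the overlap maximizing
    matches - mismatches is chosen.  At disagreeing positions the
    higher-quality base wins and the consensus quality is max - min; at
    agreeing positions the higher quality is kept.  With no acceptable
    overlap the pair is returned unmerged as a tuple.
    """
    s2 = reverse_complement(r2.seq)
    q2 = r2.qual[::-1]
    s1, q1 = r1.seq, r1.qual

    best = None  # (score, overlap)
    for o in range(min_overlap, min(len(s1), len(s2)) + 1):
        a, b = s1[-o:], s2[:o]
        matches = sum(x == y for x, y in zip(a, b))
        if o - matches > max_mismatch_frac * o:
            continue
        score = 2 * matches - o  # matches - mismatches
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return (r1, r2)
    o = best[1]
    head_s, head_q = s1[:-o] if o < len(s1) else "", q1[:-o] if o < len(s1) else ""
    cons_s, cons_q = [], []
    for i in range(o):
        b1, b2 = s1[len(s1) - o + i], s2[i]
        p1, p2 = ord(q1[len(s1) - o + i]), ord(q2[i])
        if b1 == b2:
            cons_s.append(b1)
            cons_q.append(chr(max(p1, p2)))
        else:
            hi, lo = (b1, p1), (b2, p2)
            if p2 > p1:
                hi, lo = (b2, p2), (b1, p1)
            cons_s.append(hi[0])
            cons_q.append(chr(max(hi[1] - lo[1] + 33, 33)))
    tail_s, tail_q = s2[o:], q2[o:]
    return Read(r1.name.removesuffix("/1"), head_s + "".join(cons_s) + tail_s,
                head_q + "".join(cons_q) + tail_q)


# ----------------------------------------------------------------- alignment

_CIGAR_RE = re.compile(r"(\d+)([=XIDS])")


def align_to_amplicon(
    read: Read,
    amplicon: str,
    max_divergence: float = 0.2,
) -> Optional[AlignedRead]:
    """Gapped infix alignment of a read against the amplicon via edlib.

    Returns None when the best alignment diverges by more than
    ``max_divergence`` of the read length.
    """
    res = edlib.align(read.seq, amplicon, mode="HW", task="path")
    if res["editDistance"] < 0 or res["editDistance"] > max_divergence * len(read.seq):
        return None
    ref_start = res["locations"][0][0]
    cigar = []
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        op = "M" if op in "=X" else op
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))
    return AlignedRead(
        name=read.name,
        query=read.seq,
        ref_start=ref_start,
        cigar=tuple(cigar),
        mapq=60,
        qual=read.qual,
    )


# -------------------------------------------------------------------- pileup

def build_pileup(
    aligned_reads: Iterable[AlignedRead],
    region: tuple[int, int],
    ref: str,
    min_mapq: int = 20,
    min_baseq: int = 30,
) -> list[PileupColumn]:
    """Quality-filtered pileup over ``region`` (0-based half-open).

    A base contributes iff its read's mapping quality is >= ``min_mapq`` and
    its base quality is >= ``min_baseq``; deleted positions contribute
    nothing.  A column is emitted for every region position.
    """
    start, end = region
    if end <= start:
        raise ValueError("empty pileup region")
    if end > len(ref):
        raise ValueError("region extends past the reference")
    counts = [dict.fromkeys("ACGT", 0) for _ in range(end - start)]
    for ar in aligned_reads:
        if ar.mapq < min_mapq:
            continue
        quals = ar.quals_or_default()
        qpos, rpos = 0, ar.ref_start
        for op, ln in ar.cigar:
            if op == "M":
                for i in range(ln):
                    rp = rpos + i
                    if start <= rp < end and quals[qpos + i] >= min_baseq:
                        b = ar.query[qpos + i]
                        if b in "ACGT":
                            counts[rp - start][b] += 1
                qpos += ln
                rpos += ln
            elif op in "IS":
                qpos += ln
            elif op == "D":
                rpos += ln
    return [
        PileupColumn(ref_pos=start + i, ref_base=ref[start + i], counts=counts[i])
        for i in range(end - start)
    ]


def conversion_rate(column: PileupColumn, from_base: str, to_base: str) -> Optional[float]:
    """Fraction of filtered bases converted ``from_base`` -> ``to_base``.

    The column must sit on a reference ``from_base``.  Zero depth yields
    None (missing), never 0: an uncovered position is unknown, not unedited.
    """
    if column.ref_base != from_base:
        raise ValueError(
            f"column at {column.ref_pos} has reference {column.ref_base}, not {from_base}"
        )
    d = column.depth
    if d == 0:
        return None
    return column.counts.get(to_base, 0) / d


def protospacer_profile(
    pileup: Sequence[PileupColumn],
    site: TargetSite,
    edit_type: str = "A>G",
) -> EditingProfile:
    """Per-protospacer-position conversion rates from a pileup.

    For a minus-strand site the reference is walked 3'->5' and bases are
    complemented, so position 1 is always the PAM-distal base of the
    protospacer strand; the resulting profile is identical however the site
    is annotated on the amplicon.
    """
    if edit_type not in {"A>G", "C>T"}:
        raise ValueError("edit_type must be 'A>G' or 'C>T'")
    cols = {c.ref_pos: c for c in pileup}
    lo = min(site.ref_index(1), site.ref_index(20))
    hi = max(site.ref_index(1), site.ref_index(20))
    if lo not in cols or hi not in cols:
        raise ValueError("target site not inside the pileup region")
    from_b, to_b = edit_type.split(">")
    rates: dict[int, float] = {}
    depths: dict[int, int] = {}
    no_depth = set()
    for p in range(1, 21):
        col = cols[site.ref_index(p)]
        proto_base = col.ref_base if site.strand == "+" else complement(col.ref_base)
        if proto_base != from_b:
            continue
        if site.strand == "+":
            r = conversion_rate(col, from_b, to_b)
        else:
            r = conversion_rate(col, complement(from_b), complement(to_b))
        if r is None:
            no_depth.add(p)
        else:
            rates[p] = r
            depths[p] = col.depth
    return EditingProfile(site=site, edit_type=edit_type, rates=rates,
                          depths=depths, no_depth_positions=frozenset(no_depth))


# -------------------------------------------------------------------- indels

def indel_frequency(
    aligned_reads: Iterable[AlignedRead],
    protospacer_interval: tuple[int, int],
    min_mapq: int = 20,
) -> IndelStats:
    """Fraction of mapped reads with >= 1 inserted or deleted base whose
    CIGAR op overlaps the protospacer interval (0-based half-open).

    Indel ops count irrespective of base quality — the statistic is
    read-level — but the mapping-quality filter still applies.
    """
    lo, hi = protospacer_interval
    total = 0
    with_indel = 0
    for ar in aligned_reads:
        if ar.mapq < min_mapq:
            continue
        total += 1
        rpos = ar.ref_start
        hit = False
        for op, ln in ar.cigar:
            if op == "M":
                rpos += ln
            elif op == "D":
                if rpos < hi and rpos + ln > lo:
                    hit = True
                rpos += ln
            elif op == "I":
                # inserted bases sit between rpos-1 and rpos
                if lo <= rpos <= hi:
                    hit = True
            # S consumes query only
        if hit:
            with_indel += 1
    return IndelStats(indel_reads=with_indel, total_reads=total)


# -------------------------------------------------------------------- summary

def window_summary(profiles: Sequence[EditingProfile]) -> pd.DataFrame:
    """Mean and standard error of the conversion rate per protospacer
    position, across sites.  A site lacking the editable base at a position
    is excluded from that position's average; positions present in no
    profile are absent."""
    rows = []
    for p in range(1, 21):
        vals = [prof.rates[p] for prof in profiles if p in prof.rates]
        if not vals:
            continue
        arr = np.asarray(vals, dtype=float)
        se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        rows.append({
            "position": p,
            "mean_rate": float(arr.mean()),
            "se": se,
            "n_sites": len(arr),
        })
    return pd.DataFrame(rows, columns=["position", "mean_rate", "se", "n_sites"])
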