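"""Format plumbing: FASTA/FASTQ/TSV/JSON/VCF/SAM readers and writers.

Standard formats go through the standard libraries (Bio.SeqIO for FASTA/FASTQ
parsing, pysam for SAM and VCF); tabular outputs are headered TSV with
``#``-prefixed metadata comment lines so that every artifact records the tool
version, seed and configuration hash that produced it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Read",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_features_tsv",
    "write_features_tsv",
    "read_sites_tsv",
    "write_sites_tsv",
    "write_tsv",
    "read_tsv",
    "write_vcf",
    "read_vcf",
    "read_sam",
    "config_hash",
    "metadata_lines",
]

PHRED_OFFSET = 33


@dataclass(frozen=True)
class Read:
    """One sequencing read (FASTQ record)."""

    name: str
    seq: str
    qual: str  # Phred+33 encoded, same length as seq

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.name}: seq/qual length mismatch")

    @property
    def quals(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.qual]


def qual_char(q: int) -> str:
    return chr(q + PHRED_OFFSET)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(qual_char(q) for q in rec.letter_annotations["phred_quality"])
        out.append(Read(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path: str | Path, reads: Iterable[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


# ----------------------------------------------------------------- TSV tables

def config_hash(params: dict) -> str:
    """Stable short hash of a parameter dictionary."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def metadata_lines(seed: Optional[int] = None, params: Optional[dict] = None) -> list[str]:
    from bepipe import __version__

    lines = [f"# bepipe {__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params is not None:
        lines.append(f"# config_hash={config_hash(params)}")
    return lines


def write_tsv(
    path: str | Path,
    df: pd.DataFrame,
    seed: Optional[int] = None,
    params: Optional[dict] = None,
) -> None:
    with open(path, "w") as fh:
        for line in metadata_lines(seed, params):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


FEATURE_COLUMNS = ["name", "start", "end", "strand", "kind"]


def write_features_tsv(path: str | Path, features) -> None:
    df = pd.DataFrame([
        {"name": f.name, "start": f.start, "end": f.end, "strand": f.strand, "kind": f.kind}
        for f in features
    ], columns=FEATURE_COLUMNS)
    write_tsv(path, df)


def read_features_tsv(path: str | Path):
    from bepipe.refmodel import GeneFeature

    df = read_tsv(path)
    return tuple(
        GeneFeature(r["name"], int(r["start"]), int(r["end"]), r["strand"], r["kind"])
        for _, r in df.iterrows()
    )


SITE_COLUMNS = ["name", "protospacer", "pam", "ref_name", "position", "strand"]


def write_sites_tsv(path: str | Path, sites: dict) -> None:
    """``sites`` maps a site name to a TargetSite."""
    df = pd.DataFrame([
        {"name": n, "protospacer": s.protospacer, "pam": s.pam,
         "ref_name": s.ref_name, "position": s.position, "strand": s.strand}
        for n, s in sites.items()
    ], columns=SITE_COLUMNS)
    write_tsv(path, df)


def read_sites_tsv(path: str | Path) -> dict:
    from bepipe.refmodel import TargetSite

    df = read_tsv(path)
    return {
        r["name"]: TargetSite(r["protospacer"], r["pam"], r["ref_name"],
                              int(r["position"]), r["strand"])
        for _, r in df.iterrows()
    }


# ------------------------------------------------------------------------ VCF

def write_vcf(path: str | Path, records, sample: str = "sample") -> None:
    """Write VariantRecords as a minimal VCF v4.2 with DP/AD in the sample
    column.  Records are sorted by (chrom, pos)."""
    from bepipe import __version__

    records = sorted(records, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    chroms = sorted({v.chrom for v in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=bepipe {__version__}\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for v in records:
            ref_count = max(v.depth - v.alt_count, 0)
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                f"DP:AD\t{v.depth}:{ref_count},{v.alt_count}\n"
            )


def read_vcf(path: str | Path, sample: str = "", caller: str = ""):
    """Read a (possibly empty) VCF into VariantRecords via pysam."""
    import pysam

    from bepipe.offtarget import VariantRecord

    out = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1:
                    continue  # SNVs only
                depth, alt_count = 0, 0
                if sample_names:
                    fmt = rec.samples[sample_names[0]]
                    dp = fmt.get("DP")
                    ad = fmt.get("AD")
                    depth = int(dp) if dp is not None else 0
                    if ad is not None and len(ad) >= 2 and ad[1] is not None:
                        alt_count = int(ad[1])
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref, alt,
                                         depth=depth, alt_count=alt_count,
                                         sample=sample, caller=caller))
    return out


# ------------------------------------------------------------------------ SAM

def read_sam(path: str | Path):
    """Read a text SAM into AlignedReads, trusting the stored CIGAR.

    Only primary mapped records with M/I/D/S operations are returned.
    """
    import pysam

    from bepipe.insmap import AlignedRead

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.cigartuples is None or rec.query_sequence is None:
                continue
            opmap = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}
            try:
                cigar = [(opmap[op], ln) for op, ln in rec.cigartuples]
            except KeyError:
                continue  # unsupported ops (N/H/P)
            qual = (
                "".join(qual_char(q) for q in rec.query_qualities)
                if rec.query_qualities is not None
                else qual_char(37) * len(rec.query_sequence)
            )
            out.append(AlignedRead(
                name=rec.query_name,
                query=rec.query_sequence.upper(),
                ref_start=rec.reference_start,
                cigar=cigar,
                mapq=rec.mapping_quality,
                strand="-" if rec.is_reverse else "+",
                qual=qual,
            ))
    return out
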