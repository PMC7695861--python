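"""Synthetic-data generator for every pipeline input, with recorded ground truth.

The generator emulates the study conditions end to end:

* a circular "all-in-one" screening plasmid carrying an nCas9-like CDS, a
  KanR-like marker, an AmpR-like CDS disabled by a C>T premature stop at
  codon 118 (reverting the first base of the TAA back to C restores CAA/Gln),
  and an f1-like origin region;
* MuA-style random cargo insertions with a 5-bp target-site duplication;
* ampicillin selection of in-frame, in-CDS insertions weighted by a
  per-residue tolerance map;
* 2x150 bp Illumina-like reads with a two-state quality model
  (Q37 correct / Q14 error);
* amplicon reads with position-specific base conversions and 1-bp indels;
* three variant-caller output sets with controllable sensitivity and
  false-positive rates, plus shared germline variants and a paired
  uninjected-control sample.

Every generator is a pure function of (parameters, seed) and emits a
:class:`SyntheticTruth` sufficient to score the downstream stage.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from bepipe.io import Read, qual_char
from bepipe.offtarget import VariantRecord
from bepipe.refmodel import (
    CircularSequence,
    GeneFeature,
    PlasmidMap,
    TargetSite,
    aa_position_of,
    complement,
    reverse_complement,
    translate,
    STOP_CODONS,
)

__all__ = [
    "SyntheticTruth",
    "InsertionEvent",
    "CallerOutputs",
    "make_screen_plasmid",
    "simulate_insertion_library",
    "simulate_selection",
    "simulate_reads",
    "simulate_amplicon_reads",
    "simulate_caller_outputs",
    "random_dna",
    "NoSurvivorsError",
]

BASES = np.array(list("ACGT"))
Q_CORRECT = 37
Q_ERROR = 14


class NoSurvivorsError(RuntimeError):
    """Selection cannot yield any surviving colony."""


@dataclass(frozen=True)
class InsertionEvent:
    """One cargo insertion: canonical position (leftmost duplicated base,
    0-based on the plasmid) and cargo orientation."""

    position: int
    orientation: str  # '+' or '-'


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    seed: int
    true_insertions: list[InsertionEvent] = field(default_factory=list)
    true_edit_rates: dict[int, float] = field(default_factory=dict)
    true_indel_rate: float = 0.0
    true_snvs: list[VariantRecord] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        blob = {
            "seed": self.seed,
            "true_insertions": [[e.position, e.orientation] for e in self.true_insertions],
            "true_edit_rates": {str(k): v for k, v in self.true_edit_rates.items()},
            "true_indel_rate": self.true_indel_rate,
            "true_snvs": [dataclasses.asdict(v) for v in self.true_snvs],
        }
        Path(path).write_text(json.dumps(blob, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        blob = json.loads(Path(path).read_text())
        return cls(
            seed=blob["seed"],
            true_insertions=[InsertionEvent(p, o) for p, o in blob["true_insertions"]],
            true_edit_rates={int(k): v for k, v in blob["true_edit_rates"].items()},
            true_indel_rate=blob.get("true_indel_rate", 0.0),
            true_snvs=[VariantRecord(**v) for v in blob["true_snvs"]],
        )


# ------------------------------------------------------------ sequence helpers

def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _random_codons(rng: np.random.Generator, n_aa: int, gc: float) -> list[str]:
    """n_aa sense codons (no internal stops)."""
    out = []
    while len(out) < n_aa:
        codon = random_dna(rng, 3, gc)
        if codon not in STOP_CODONS:
            out.append(codon)
    return out


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """A CDS of n_codons total codons, the last one a stop."""
    return "".join(_random_codons(rng, n_codons - 1, gc)) + "TAA"


# ------------------------------------------------------------- screen plasmid

def make_screen_plasmid(
    seed: int,
    cds_len_aa: int = 1368,
    gc: float = 0.5,
    ampr_len_aa: int = 286,
    kanr_len_aa: int = 264,
    f1_len: int = 400,
    spacer: int = 120,
    stop_codon_index: int = 118,
) -> PlasmidMap:
    """Build the screening plasmid: nCas9-like CDS + KanR-like CDS + AmpR-like
    CDS with a premature stop + f1-like origin, separated by spacers.

    ``cds_len_aa`` counts codons of the nCas9-like CDS including its final
    stop.  The AmpR-like CDS carries a C>T change at ``stop_codon_index``
    turning a CAA (Gln) codon into TAA — the selection readout: A:T→G:C
    editing at that position restores translation.
    """
    if cds_len_aa < 10:
        raise ValueError("cds_len_aa must be >= 10")
    if not 1 < stop_codon_index < ampr_len_aa:
        raise ValueError("stop codon index outside the AmpR-like CDS")
    rng = np.random.default_rng(seed)

    ncas9 = _random_cds(rng, cds_len_aa, gc)
    kanr = _random_cds(rng, kanr_len_aa, gc)
    ampr_codons = _random_codons(rng, ampr_len_aa - 1, gc)
    ampr_codons[stop_codon_index - 1] = "CAA"
    ampr = "".join(ampr_codons) + "TAA"
    # the premature stop: C>T at the first base of codon 118
    i = (stop_codon_index - 1) * 3
    ampr_broken = ampr[:i] + "TAA" + ampr[i + 3:]
    f1 = random_dna(rng, f1_len, gc)

    segments = []
    features = []
    pos = 0
    for name, seq, kind in (
        ("nCas9", ncas9, "CDS"),
        ("KanR", kanr, "CDS"),
        ("AmpR", ampr_broken, "CDS"),
        ("f1", f1, "origin"),
    ):
        segments.append(random_dna(rng, spacer, gc))
        pos += spacer
        features.append(GeneFeature(name, pos, pos + len(seq), "+", kind))
        segments.append(seq)
        pos += len(seq)
    segments.append(random_dna(rng, spacer, gc))

    plasmid = PlasmidMap(
        sequence=CircularSequence("".join(segments)),
        features=tuple(features),
        premature_stop=("AmpR", stop_codon_index),
    )
    return plasmid


# ---------------------------------------------------------- insertion library

def simulate_insertion_library(
    plasmid: PlasmidMap,
    cargo: str,
    n: int,
    tsd_len: int = 5,
    seed: int = 0,
    weights: Optional[np.ndarray] = None,
) -> tuple[list[str], SyntheticTruth]:
    """Random cargo insertions into the circular plasmid.

    Positions are uniform over the plasmid (or drawn from ``weights`` to
    model hotspot bias); orientation is Bernoulli(0.5).  Each event
    duplicates ``tsd_len`` bases at the insertion point (target-site
    duplication); the canonical truth coordinate is the leftmost duplicated
    base.  Each mutated molecule is returned as a linear string rotated to
    start at the left TSD copy; it represents a circular molecule of length
    ``plasmid + cargo + tsd_len``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not cargo:
        raise ValueError("cargo must be non-empty")
    rng = np.random.default_rng(seed)
    L = len(plasmid)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (L,):
            raise ValueError("weights must have one entry per plasmid position")
        positions = rng.choice(L, size=n, p=w / w.sum())
    else:
        positions = rng.integers(0, L, size=n)
    orientations = np.where(rng.random(n) < 0.5, "+", "-")

    cargo_rc = reverse_complement(cargo)
    molecules = []
    events = []
    for p, o in zip(positions.tolist(), orientations.tolist()):
        rot = plasmid.sequence.fetch(p, p + L)  # rotation starting at p
        ins = cargo if o == "+" else cargo_rc
        molecules.append(rot[:tsd_len] + ins + rot)
        events.append(InsertionEvent(int(p), o))
    truth = SyntheticTruth(seed=seed, true_insertions=events)
    return molecules, truth


def simulate_selection(
    events: Sequence[InsertionEvent],
    tolerance: dict[int, float],
    cargo_len: int,
    n_colonies: int,
    cds: GeneFeature,
    plasmid_len: int,
    seed: int = 0,
) -> list[InsertionEvent]:
    """Ampicillin selection of the insertion library.

    An event survives with probability ``tolerance[aa]`` when it lies inside
    the nCas9-like CDS and is in frame (nucleotide offset and cargo length
    both multiples of 3); any other event never survives.  Colonies are drawn
    with replacement until ``n_colonies`` survivors accumulate.
    """
    if not events:
        raise ValueError("no insertion events to select from")
    bad = [v for v in tolerance.values() if not 0.0 <= v <= 1.0]
    if bad:
        raise ValueError("tolerance activities must lie in [0,1]")
    probs = np.zeros(len(events))
    for i, e in enumerate(events):
        off = cds.offset_of(e.position, plasmid_len)
        if off is None or off % 3 != 0 or cargo_len % 3 != 0:
            continue
        aa = off // 3 + 1
        probs[i] = tolerance.get(aa, 0.0)
    if probs.sum() == 0:
        raise NoSurvivorsError("no event has a nonzero survival probability")
    rng = np.random.default_rng(seed)
    survivors: list[InsertionEvent] = []
    while len(survivors) < n_colonies:
        i = int(rng.integers(0, len(events)))
        if rng.random() < probs[i]:
            survivors.append(events[i])
    return survivors


# ---------------------------------------------------------------------- reads

def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, str]:
    """Two-state quality model: errors get Q14, correct bases Q37."""
    n = len(seq)
    if error_rate <= 0:
        return seq, qual_char(Q_CORRECT) * n
    err = rng.random(n) < error_rate
    if not err.any():
        return seq, qual_char(Q_CORRECT) * n
    arr = np.array(list(seq))
    for i in np.flatnonzero(err):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    qual = np.where(err, qual_char(Q_ERROR), qual_char(Q_CORRECT))
    return "".join(arr), "".join(qual)


def simulate_reads(
    templates: Sequence[str] | str,
    n_reads: int,
    read_len: int = 150,
    paired: bool = False,
    insert_size: int = 300,
    error_rate: float = 0.001,
    circular: bool = True,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[Read]:
    """Uniform shotgun reads from one or more templates.

    Start positions are uniform; circular templates wrap.  For paired mode
    each fragment of ``insert_size`` yields mate 1 from its 5' end and mate 2
    as the reverse complement of its 3' end (mates are consecutive in the
    output, suffixed ``/1`` and ``/2``).  Substitution errors occur at
    ``error_rate`` and carry low (Q14) base quality.
    """
    if isinstance(templates, str):
        templates = [templates]
    span = insert_size if paired else read_len
    for t in templates:
        if len(t) < span and not circular:
            raise ValueError("template shorter than the required span")
        if len(t) < span and circular:
            raise ValueError("template shorter than the required span even with wrap")
    rng = np.random.default_rng(seed)
    out: list[Read] = []
    t_idx = rng.integers(0, len(templates), size=n_reads)
    for i in range(n_reads):
        t = templates[int(t_idx[i])]
        L = len(t)
        start = int(rng.integers(0, L if circular else L - span + 1))
        frag = (t + t)[start:start + span] if circular else t[start:start + span]
        if paired:
            r1_seq, r1_q = _apply_errors(rng, frag[:read_len], error_rate)
            r2_seq, r2_q = _apply_errors(
                rng, reverse_complement(frag[-read_len:]), error_rate
            )
            out.append(Read(f"{name_prefix}{i}/1", r1_seq, r1_q))
            out.append(Read(f"{name_prefix}{i}/2", r2_seq, r2_q))
        else:
            s, q = _apply_errors(rng, frag, error_rate)
            out.append(Read(f"{name_prefix}{i}", s, q))
    return out


# ------------------------------------------------------------- amplicon reads

def simulate_amplicon_reads(
    amplicon: str,
    site: TargetSite,
    per_position_rates: dict[int, float],
    indel_rate: float = 0.0,
    n_reads: int = 1000,
    edit_type: str = "A>G",
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[Read], SyntheticTruth]:
    """Full-length amplicon reads with position-specific base conversions.

    Each read independently converts the editable base at protospacer
    position ``p`` with probability ``per_position_rates[p]`` (strand-aware:
    for a minus-strand site the conversion appears complemented on the
    amplicon top strand), and with probability ``indel_rate`` carries a 1-bp
    insertion or deletion inside the protospacer.
    """
    if edit_type not in {"A>G", "C>T"}:
        raise ValueError("edit_type must be 'A>G' or 'C>T'")
    if site.position < 0 or site.position + 20 > len(amplicon):
        raise ValueError("target site not inside the amplicon")
    from_b, to_b = edit_type.split(">")
    rng = np.random.default_rng(seed)

    # map protospacer position -> (amplicon index, top-strand from/to)
    plan: dict[int, tuple[int, str, str]] = {}
    for p, rate in per_position_rates.items():
        if not 1 <= p <= 20:
            raise ValueError(f"protospacer position {p} outside 1..20")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate at position {p} outside [0,1]")
        idx = site.ref_index(p)
        top_from = from_b if site.strand == "+" else complement(from_b)
        top_to = to_b if site.strand == "+" else complement(to_b)
        if amplicon[idx] != top_from:
            raise ValueError(
                f"protospacer position {p}: amplicon base {amplicon[idx]} is not "
                f"editable as {edit_type} on strand {site.strand}"
            )
        plan[p] = (idx, top_from, top_to)

    proto_lo = min(site.ref_index(1), site.ref_index(20))
    proto_hi = max(site.ref_index(1), site.ref_index(20)) + 1

    reads: list[Read] = []
    for i in range(n_reads):
        seq = list(amplicon)
        for p, (idx, _, top_to) in plan.items():
            if rng.random() < per_position_rates[p]:
                seq[idx] = top_to
        if indel_rate > 0 and rng.random() < indel_rate:
            j = int(rng.integers(proto_lo, proto_hi))
            if rng.random() < 0.5:
                del seq[j]
            else:
                seq.insert(j, str(rng.choice(BASES)))
        s, q = _apply_errors(rng, "".join(seq), error_rate)
        reads.append(Read(f"amp{i}", s, q))

    truth = SyntheticTruth(
        seed=seed,
        true_edit_rates=dict(per_position_rates),
        true_indel_rate=indel_rate,
    )
    return reads, truth


# -------------------------------------------------------------- caller output

@dataclass
class CallerOutputs:
    """Emulated per-caller SNV sets for an edited sample and its paired
    uninjected control."""

    edited: dict[str, list[VariantRecord]]
    control: dict[str, list[VariantRecord]]
    germline: list[VariantRecord]

    @property
    def caller_names(self) -> list[str]:
        return list(self.edited)

    def control_union(self) -> list[VariantRecord]:
        seen: dict = {}
        for recs in self.control.values():
            for v in recs:
                seen.setdefault(v.key, v)
        return list(seen.values())


def _random_snv(rng: np.random.Generator, chrom: str, genome_len: int,
                sample: str, caller: str, p_cg_ta: Optional[float] = None) -> VariantRecord:
    pos = int(rng.integers(1, genome_len + 1))
    if p_cg_ta is not None and rng.random() < p_cg_ta:
        ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
    else:
        while True:
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            # the signature branch owns C>T/G>A; keep the classes exclusive
            if p_cg_ta is None or (ref, alt) not in {("C", "T"), ("G", "A")}:
                break
    depth = int(rng.integers(20, 60))
    alt_count = int(rng.integers(5, depth + 1))
    return VariantRecord(chrom, pos, ref, alt, depth=depth,
                         alt_count=alt_count, sample=sample, caller=caller)


def make_true_snvs(
    n: int,
    genome_len: int,
    seed: int = 0,
    chrom: str = "chr1",
    p_cg_ta: float = 0.92,
) -> list[VariantRecord]:
    """True editor-induced SNVs with a deaminase-like substitution signature
    (default 92% C:G>T:A, the signature of cytosine deamination)."""
    rng = np.random.default_rng(seed)
    out, seen = [], set()
    while len(out) < n:
        v = _random_snv(rng, chrom, genome_len, sample="edited", caller="truth",
                        p_cg_ta=p_cg_ta)
        if v.key not in seen:
            seen.add(v.key)
            out.append(v)
    return out


def simulate_caller_outputs(
    true_snvs: Sequence[VariantRecord],
    genome_len: int,
    sensitivity: Sequence[float] = (0.9, 0.9, 0.9),
    fp_rate: Sequence[float] = (2e-6, 2e-6, 2e-6),
    n_germline: int = 50,
    seed: int = 0,
    caller_names: Sequence[str] = ("caller1", "caller2", "caller3"),
) -> CallerOutputs:
    """Emulate three somatic-caller output sets for a GOTI-style pair.

    Each caller reports each true SNV independently with its sensitivity and
    adds Poisson(fp_rate x genome_len) unique false positives.  Germline-like
    variants are shared across all callers and both samples, so the paired
    control subtracts them from the consensus.
    """
    if len(sensitivity) != len(caller_names) or len(fp_rate) != len(caller_names):
        raise ValueError("need one sensitivity and fp_rate per caller")
    rng = np.random.default_rng(seed)
    chrom = true_snvs[0].chrom if true_snvs else "chr1"
    true_keys = {v.key for v in true_snvs}

    germline = []
    seen = set(true_keys)
    while len(germline) < n_germline:
        v = _random_snv(rng, chrom, genome_len, sample="germline", caller="all")
        if v.key not in seen:
            seen.add(v.key)
            germline.append(v)

    edited: dict[str, list[VariantRecord]] = {}
    control: dict[str, list[VariantRecord]] = {}
    for name, s, fp in zip(caller_names, sensitivity, fp_rate):
        calls = [
            dataclasses.replace(v, sample="edited", caller=name)
            for v in true_snvs
            if rng.random() < s
        ]
        n_fp = int(rng.poisson(fp * genome_len))
        fp_seen = set(seen)
        while n_fp > 0:
            v = _random_snv(rng, chrom, genome_len, sample="edited", caller=name)
            if v.key not in fp_seen:
                fp_seen.add(v.key)
                calls.append(v)
                n_fp -= 1
        calls += [dataclasses.replace(v, sample="edited", caller=name) for v in germline]
        edited[name] = calls
        control[name] = [
            dataclasses.replace(v, sample="control", caller=name) for v in germline
        ]
    return CallerOutputs(edited=edited, control=control, germline=germline)
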