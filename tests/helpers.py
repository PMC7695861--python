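"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the scanner oracle is
a naive per-window loop, and the breakpoint oracle is exhaustive junction
substring search over the read set.
"""
from __future__ import annotations

import numpy as np

from bepipe.io import Read
from bepipe.refmodel import reverse_complement


def brute_force_scan(genome: str, protospacer: str, pam: str, mode: str,
                     max_mm: int = 3, seed_len: int = 12,
                     seed_max_mm: int = 2, nonseed_max_mm: int = 3):
    """Naive enumeration of every 23-nt window on both strands."""
    out = []
    n = len(genome)
    for strand in "+-":
        s = genome if strand == "+" else reverse_complement(genome)
        for j in range(n - 22):
            w = s[j:j + 23]
            if w[22] != "G":
                continue
            if pam == "NGG" and w[21] != "G":
                continue
            if pam == "NRG" and w[21] not in "AG":
                continue
            mm = sum(a != b for a, b in zip(w[:20], protospacer))
            seed_mm = sum(a != b for a, b in
                          zip(w[20 - seed_len:20], protospacer[20 - seed_len:]))
            if mode == "total_mm":
                keep = mm <= max_mm
            else:
                keep = seed_mm <= seed_max_mm and (mm - seed_mm) <= nonseed_max_mm
            if keep:
                out.append((j if strand == "+" else n - 23 - j, strand, mm))
    return sorted(out)


def junction_substring_oracle(reads, plasmid, cargo: str, tsd_len: int,
                              backbone_flank: int = 30, cargo_flank: int = 20):
    """Positions whose backbone|cargo junction string occurs verbatim in the
    read set (either strand, either cargo orientation, either junction side)."""
    haystack = "\n".join([r.seq for r in reads]
                         + [reverse_complement(r.seq) for r in reads])
    cargo_rc = reverse_complement(cargo)
    L = len(plasmid)
    found = set()
    for p in range(L):
        left_bb = plasmid.sequence.fetch(p + tsd_len - backbone_flank, p + tsd_len)
        right_bb = plasmid.sequence.fetch(p, p + backbone_flank)
        for c in (cargo, cargo_rc):
            if (left_bb + c[:cargo_flank]) in haystack:
                found.add(p)
                break
            if (c[-cargo_flank:] + right_bb) in haystack:
                found.add(p)
                break
    return found


def junction_reads(molecules, cargo_len: int, tsd_len: int, read_len: int = 150,
                   seed: int = 0, reads_per_event: int = 2,
                   min_backbone: int = 43, min_cargo: int = 33):
    """Junction-spanning reads with a random split between backbone and cargo
    bases, keeping both portions comfortably above the detection thresholds."""
    rng = np.random.default_rng(seed)
    reads = []
    for i, mol in enumerate(molecules):
        L = len(mol)
        doubled = mol + mol
        for j in range(reads_per_event):
            junction = tsd_len if j % 2 == 0 else tsd_len + cargo_len
            bb = int(rng.integers(min_backbone, read_len - min_cargo + 1))
            if j % 2 == 0:  # left junction: backbone upstream, cargo downstream
                start = (junction - bb) % L
            else:  # right junction: cargo upstream, backbone downstream
                start = (junction - (read_len - bb)) % L
            reads.append(Read(f"j{i}_{j}", doubled[start:start + read_len],
                              "F" * read_len))
    return reads


def decoy_reads(plasmid, cargo: str, n: int = 20, read_len: int = 150,
                seed: int = 99):
    """Reads carrying no junction: pure backbone, pure cargo, and random DNA."""
    rng = np.random.default_rng(seed)
    out = []
    L = len(plasmid)
    dbl = plasmid.sequence.seq * 2
    for i in range(n):
        kind = i % 3
        if kind == 0:
            s = int(rng.integers(0, L))
            seq = dbl[s:s + read_len]
        elif kind == 1 and len(cargo) >= read_len:
            s = int(rng.integers(0, len(cargo) - read_len + 1))
            seq = cargo[s:s + read_len]
        else:
            seq = "".join(rng.choice(list("ACGT"), size=read_len))
        out.append(Read(f"decoy{i}", seq, "F" * read_len))
    return out
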