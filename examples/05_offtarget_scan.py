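"""Guide-dependent off-target prediction: protospacer mismatch scanning
with a PAM constraint, in total-mismatch and seed-aware modes.

A 20-kb genome gets planted sites at 0-4 mismatches from the guide; the
scanner enumerates 23-nt windows on both strands whose last three bases
match the NRG PAM and whose protospacer mismatches stay within the limits
(<=3 total, or <=2 in the 12-nt PAM-proximal seed and <=3 elsewhere).
"""
import numpy as np

from bepipe import simkit
from bepipe.offtarget import predict_guide_dependent_sites
from bepipe.refmodel import TargetSite, reverse_complement

SEED = 1
rng = np.random.default_rng(SEED)
guide = simkit.random_dna(rng, 20)
genome = simkit.random_dna(rng, 20000)

for i, n_mm in enumerate(range(5)):
    variant = list(guide)
    for j in range(n_mm):
        variant[2 + 4 * j] = "A" if variant[2 + 4 * j] != "A" else "G"
    block = "".join(variant) + "AGG"
    if i % 2 == 1:
        block = reverse_complement(block)  # plant on the minus strand
    genome = genome[:2000 + i * 3000] + block + genome[2000 + i * 3000:]

site = TargetSite(guide, "NRG", "genome", 0, "+")
for mode in ("total_mm", "seed_aware"):
    hits = predict_guide_dependent_sites(genome, site, mode=mode)
    print(f"{mode:>10}: {len(hits)} candidate site(s)")
    for h in hits:
        print(f"    pos {h.position:>6}  strand {h.strand}  "
              f"{h.mismatches} mismatch(es)")
# The exact site and low-mismatch plants are reported on both strands; the
# 4-mismatch plant is rejected by the <=3 total-mismatch rule, and the
# seed-aware mode additionally drops sites with >2 seed mismatches.
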