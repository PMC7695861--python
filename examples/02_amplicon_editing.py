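"""Amplicon editing quantification: per-protospacer-position A>G rates
and indel frequency from deep-sequencing reads.

Reads are simulated with known conversion rates at protospacer positions
3/5/8 plus a 3% 1-bp indel rate, aligned to the amplicon, piled up under
mapq>=20 / baseq>=30 filters, and quantified.
"""
from bepipe import editquant, simkit
from bepipe.cli import make_edited_amplicon

SEED = 1
TRUTH = {3: 0.10, 5: 0.86, 8: 0.30}

amplicon, site = make_edited_amplicon(200, "A", positions=sorted(TRUTH),
                                      seed=SEED)
reads, _ = simkit.simulate_amplicon_reads(
    amplicon, site, TRUTH, indel_rate=0.03, n_reads=5000,
    error_rate=0.001, seed=SEED + 1)

aligned = [editquant.align_to_amplicon(r, amplicon) for r in reads]
pileup = editquant.build_pileup(aligned, (site.position, site.position + 23),
                                amplicon)
profile = editquant.protospacer_profile(pileup, site, edit_type="A>G")
indels = editquant.indel_frequency(aligned, (site.position, site.position + 20))

print("position  truth  estimated")
for p in sorted(profile.rates):
    print(f"  A{p:<6} {TRUTH[p]:.2f}   {profile.rates[p]:.3f}")
print(f"indel frequency: {indels.frequency:.4f}  (truth 0.03)")
# Estimates track the true per-position conversion rates to within binomial
# sampling error at 5,000 reads; only protospacer positions whose reference
# base is an A are reported.
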