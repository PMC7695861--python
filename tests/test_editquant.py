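"""Pair merging, quality-filtered pileups, conversion rates, indels."""
import numpy as np
import pytest

from bepipe import editquant, simkit
from bepipe.cli import make_edited_amplicon
from bepipe.editquant import (
    PileupColumn,
    align_to_amplicon,
    build_pileup,
    conversion_rate,
    indel_frequency,
    merge_read_pairs,
    protospacer_profile,
    window_summary,
)
from bepipe.insmap import AlignedRead
from bepipe.io import Read, qual_char
from bepipe.refmodel import TargetSite, reverse_complement


def _pair_from(template, o):
    """A read pair whose mates overlap by exactly o bases."""
    r1 = Read("p/1", template[:60], "F" * 60)
    frag2 = template[60 - o:120 - o]
    r2 = Read("p/2", reverse_complement(frag2), "F" * 60)
    return r1, r2


class TestMerge:
    TEMPLATE = simkit.random_dna(np.random.default_rng(123), 129)

    def test_identical_overlapping_mates_merge_to_template(self):
        r1, r2 = _pair_from(self.TEMPLATE, 30)
        m = merge_read_pairs(r1, r2)
        assert isinstance(m, Read)
        assert m.seq == self.TEMPLATE[:90]

    def test_overlap_below_minimum_not_merged(self):
        r1, r2 = _pair_from(self.TEMPLATE, 10)
        out = merge_read_pairs(r1, r2, min_overlap=11)
        assert isinstance(out, tuple)

    def test_overlap_exactly_at_minimum_merges(self):
        r1, r2 = _pair_from(self.TEMPLATE, 11)
        assert isinstance(merge_read_pairs(r1, r2, min_overlap=11), Read)

    def test_disagreement_resolved_by_quality(self):
        r1, r2 = _pair_from(self.TEMPLATE, 30)
        # corrupt one overlap base in mate 1 and mark it low quality
        i = 40
        wrong = "A" if r1.seq[i] != "A" else "C"
        q = qual_char(14)
        r1bad = Read(r1.name, r1.seq[:i] + wrong + r1.seq[i + 1:],
                     r1.qual[:i] + q + r1.qual[i + 1:])
        m = merge_read_pairs(r1bad, r2)
        assert isinstance(m, Read)
        assert m.seq[i] == self.TEMPLATE[i]  # Q37 mate-2 base wins
        assert m.quals[i] == 37 - 14  # consensus quality is max - min


class TestPileup:
    def _aligned(self, seq, qual, ref_start=0, mapq=60):
        return AlignedRead("r", seq, ref_start, (("M", len(seq)),), mapq,
                           qual=qual)

    def test_high_quality_bases_all_count(self):
        ref = "ACGTACGTAC"
        reads = [self._aligned(ref, "F" * 10) for _ in range(7)]
        cols = build_pileup(reads, (0, 10), ref)
        assert all(c.depth == 7 for c in cols)
        assert all(c.counts[c.ref_base] == 7 for c in cols)

    def test_low_quality_bases_excluded(self):
        ref = "ACGTACGTAC"
        q14 = qual_char(14) * 10
        reads = [self._aligned(ref, q14) for _ in range(5)]
        cols = build_pileup(reads, (0, 10), ref, min_baseq=30)
        assert all(c.depth == 0 for c in cols)

    def test_low_mapq_reads_excluded(self):
        ref = "ACGTACGTAC"
        reads = [self._aligned(ref, "F" * 10, mapq=5)]
        cols = build_pileup(reads, (0, 10), ref, min_mapq=20)
        assert all(c.depth == 0 for c in cols)

    def test_mixed_alt_counts(self):
        ref = "C" * 5
        reads = [self._aligned("CCTCC" if i < 60 else ref, "F" * 5)
                 for i in range(100)]
        cols = build_pileup(reads, (0, 5), ref)
        assert cols[2].counts["T"] == 60 and cols[2].depth == 100
        assert conversion_rate(cols[2], "C", "T") == pytest.approx(0.60)

    def test_lowering_baseq_never_decreases_depth(self):
        rng = np.random.default_rng(3)
        ref = simkit.random_dna(rng, 50)
        reads = simkit.simulate_reads(ref, 40, read_len=50, error_rate=0.05,
                                      circular=False, seed=4)
        aligned = [self._aligned(r.seq, r.qual) for r in reads]
        d30 = sum(c.depth for c in build_pileup(aligned, (0, 50), ref,
                                                min_baseq=30))
        d10 = sum(c.depth for c in build_pileup(aligned, (0, 50), ref,
                                                min_baseq=10))
        assert d10 >= d30

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            build_pileup([], (5, 5), "ACGTACGT")


class TestConversionRate:
    def test_no_conversion(self):
        col = PileupColumn(0, "C", {"A": 0, "C": 100, "G": 0, "T": 0})
        assert conversion_rate(col, "C", "T") == 0.0

    def test_zero_depth_is_missing(self):
        col = PileupColumn(0, "C", dict.fromkeys("ACGT", 0))
        assert conversion_rate(col, "C", "T") is None

    def test_wrong_reference_rejected(self):
        col = PileupColumn(0, "A", {"A": 10, "C": 0, "G": 0, "T": 0})
        with pytest.raises(ValueError):
            conversion_rate(col, "C", "T")


class TestProtospacerProfile:
    def _profile_from_sim(self, strand, seed=17):
        rates = {3: 0.1, 5: 0.8, 8: 0.35}
        amp, site = make_edited_amplicon(200, "A", positions=sorted(rates),
                                         seed=5, strand=strand)
        reads, _ = simkit.simulate_amplicon_reads(
            amp, site, rates, n_reads=1500, seed=seed)
        aligned = [align_to_amplicon(r, amp) for r in reads]
        pile = build_pileup(aligned, (0, len(amp)), amp)
        return rates, protospacer_profile(pile, site, "A>G")

    def test_rates_recovered_at_edited_positions_only(self):
        rates, prof = self._profile_from_sim("+")
        assert set(prof.rates) == set(rates)  # only editable As appear
        for p, r in rates.items():
            sd = np.sqrt(r * (1 - r) / 1500)
            assert abs(prof.rates[p] - r) < max(3 * sd, 0.01)

    def test_strand_invariance(self):
        _, plus = self._profile_from_sim("+")
        _, minus = self._profile_from_sim("-")
        for p in plus.rates:
            assert minus.rates[p] == pytest.approx(plus.rates[p], abs=0.05)

    def test_no_editable_base_gives_empty_profile(self):
        amp = "GGTTCCGGTTCCGGTTCCGG" * 3  # no A anywhere
        site = TargetSite(amp[10:30], "NGG", "a", 10, "+")
        cols = build_pileup(
            [AlignedRead("r", amp, 0, (("M", len(amp)),), 60, qual="F" * len(amp))],
            (0, len(amp)), amp)
        prof = protospacer_profile(cols, site, "A>G")
        assert prof.rates == {}

    def test_site_outside_region_rejected(self):
        amp = "ACGT" * 20
        site = TargetSite("ACGT" * 5, "NGG", "a", 70, "+")
        cols = build_pileup(
            [AlignedRead("r", amp[:40], 0, (("M", 40),), 60, qual="F" * 40)],
            (0, 40), amp)
        with pytest.raises(ValueError):
            protospacer_profile(cols, site, "A>G")


class TestIndels:
    def _read(self, cigar, ref_start=0):
        qlen = sum(l for op, l in cigar if op in "MIS")
        return AlignedRead("r", "A" * qlen, ref_start, cigar, 60)

    def test_no_indels(self):
        reads = [self._read((("M", 100),)) for _ in range(10)]
        assert indel_frequency(reads, (40, 60)).frequency == 0.0

    def test_deletion_inside_protospacer_counts(self):
        reads = [self._read((("M", 50), ("D", 1), ("M", 49)))
                 for _ in range(5)]
        reads += [self._read((("M", 100),)) for _ in range(45)]
        stats = indel_frequency(reads, (40, 60))
        assert stats.indel_reads == 5 and stats.total_reads == 50
        assert stats.frequency == pytest.approx(0.10)

    def test_deletion_outside_protospacer_not_counted(self):
        reads = [self._read((("M", 10), ("D", 2), ("M", 90)))]
        assert indel_frequency(reads, (40, 60)).indel_reads == 0

    def test_insertion_inside_counts(self):
        reads = [self._read((("M", 50), ("I", 1), ("M", 50)))]
        assert indel_frequency(reads, (40, 60)).indel_reads == 1

    def test_recovery_from_simulated_amplicon(self):
        rates = {5: 0.3}
        amp, site = make_edited_amplicon(200, "A", positions=[5], seed=6)
        reads, truth = simkit.simulate_amplicon_reads(
            amp, site, rates, indel_rate=0.08, n_reads=2000, seed=18)
        aligned = [align_to_amplicon(r, amp) for r in reads]
        lo = site.position
        stats = indel_frequency(aligned, (lo, lo + 20))
        sd = np.sqrt(0.08 * 0.92 / 2000)
        assert abs(stats.frequency - 0.08) < 3 * sd + 0.01


class TestWindowSummary:
    def _profile(self, rates):
        site = TargetSite("A" * 20, "NGG", "a", 0, "+")
        return editquant.EditingProfile(site, "A>G", rates,
                                        {p: 100 for p in rates})

    def test_single_profile_mean_is_profile(self):
        df = window_summary([self._profile({5: 0.4, 7: 0.2})])
        assert df.set_index("position")["mean_rate"].to_dict() == {5: 0.4, 7: 0.2}
        assert (df["se"] == 0).all()

    def test_mean_across_sites(self):
        df = window_summary([self._profile({6: 0.2}), self._profile({6: 0.4})])
        row = df.set_index("position").loc[6]
        assert row["mean_rate"] == pytest.approx(0.3)
        assert row["n_sites"] == 2

    def test_absent_positions_excluded(self):
        df = window_summary([self._profile({5: 0.4}), self._profile({9: 0.1})])
        assert set(df["position"]) == {5, 9}
        assert (df.set_index("position")["n_sites"] == 1).all()
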