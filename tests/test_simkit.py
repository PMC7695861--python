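"""Synthetic-data generator: determinism, construction rules, and the
statistical properties the downstream stages rely on."""
import numpy as np
import pytest
from scipy import stats

from bepipe import refmodel, simkit
from bepipe.refmodel import reverse_complement, translate


class TestScreenPlasmid:
    def test_deterministic(self):
        a = simkit.make_screen_plasmid(seed=3, cds_len_aa=50)
        b = simkit.make_screen_plasmid(seed=3, cds_len_aa=50)
        assert a.sequence.seq == b.sequence.seq
        assert a.features == b.features

    def test_premature_stop_reverts_to_gln(self, small_plasmid):
        fname, idx = small_plasmid.premature_stop
        codon = small_plasmid.codon(fname, idx)
        assert translate(codon) == "*"
        new, res = refmodel.predict_edit_consequence(codon, 1, "T>C")
        assert (new, res) == ("CAA", "Q")

    def test_features_disjoint_and_cds_clean(self, small_plasmid):
        feats = sorted(small_plasmid.features, key=lambda f: f.start)
        for f1, f2 in zip(feats, feats[1:]):
            assert f1.end <= f2.start
        # nCas9-like CDS has no internal stop
        protein = translate(small_plasmid.feature_sequence("nCas9"))
        assert "*" not in protein[:-1] and protein[-1] == "*"

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            simkit.make_screen_plasmid(seed=0, cds_len_aa=5)


class TestInsertionLibrary:
    def test_length_arithmetic(self, small_plasmid, cargo):
        for tsd in (0, 5):
            mols, _ = simkit.simulate_insertion_library(
                small_plasmid, cargo, n=1, tsd_len=tsd, seed=1)
            assert len(mols[0]) == len(small_plasmid) + len(cargo) + tsd

    def test_tsd_structure(self, small_plasmid, cargo):
        mols, truth = simkit.simulate_insertion_library(
            small_plasmid, cargo, n=4, tsd_len=5, seed=2)
        for mol, ev in zip(mols, truth.true_insertions):
            tsd = small_plasmid.sequence.fetch(ev.position, ev.position + 5)
            ins = cargo if ev.orientation == "+" else reverse_complement(cargo)
            assert mol.startswith(tsd + ins + tsd)

    def test_positions_uniform_chisquare(self, small_plasmid):
        _, truth = simkit.simulate_insertion_library(
            small_plasmid, "ACGTACGTACGTACGT", n=10000, tsd_len=0, seed=5)
        pos = np.array([e.position for e in truth.true_insertions])
        counts, _ = np.histogram(pos, bins=10, range=(0, len(small_plasmid)))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_hotspot_weights(self, small_plasmid):
        w = np.zeros(len(small_plasmid))
        w[42] = 1.0
        _, truth = simkit.simulate_insertion_library(
            small_plasmid, "ACGTACGTACGTACGT", n=20, seed=5, weights=w)
        assert all(e.position == 42 for e in truth.true_insertions)


class TestSelection:
    def _events(self, small_plasmid, n=400, seed=8):
        _, truth = simkit.simulate_insertion_library(
            small_plasmid, "ACG", n=n, tsd_len=5, seed=seed)
        return truth.true_insertions

    def test_only_tolerated_residues_survive(self, small_plasmid):
        cds = small_plasmid.feature("nCas9")
        events = self._events(small_plasmid)
        tol = {aa: 1.0 for aa in range(40, 61)}
        survivors = simkit.simulate_selection(
            events, tol, cargo_len=300, n_colonies=10,
            cds=cds, plasmid_len=len(small_plasmid), seed=1)
        for s in survivors:
            off = cds.offset_of(s.position, len(small_plasmid))
            assert off is not None and 40 <= off // 3 + 1 <= 60 and off % 3 == 0

    def test_out_of_frame_cargo_never_survives(self, small_plasmid):
        cds = small_plasmid.feature("nCas9")
        events = self._events(small_plasmid)
        tol = {aa: 1.0 for aa in range(1, 201)}
        with pytest.raises(simkit.NoSurvivorsError):
            simkit.simulate_selection(events, tol, cargo_len=301, n_colonies=5,
                                      cds=cds, plasmid_len=len(small_plasmid),
                                      seed=1)

    def test_all_zero_tolerance_errors(self, small_plasmid):
        cds = small_plasmid.feature("nCas9")
        events = self._events(small_plasmid)
        with pytest.raises(simkit.NoSurvivorsError):
            simkit.simulate_selection(events, {}, cargo_len=300, n_colonies=1,
                                      cds=cds, plasmid_len=len(small_plasmid),
                                      seed=1)

    def test_survivor_frequency_tracks_tolerance(self, small_plasmid):
        """Survivor residue frequencies follow the tolerance map
        (multinomial expectation, in-frame events hit ~1/3 of offsets)."""
        cds = small_plasmid.feature("nCas9")
        events = self._events(small_plasmid, n=3000, seed=12)
        tol = {aa: (0.9 if aa <= 100 else 0.1) for aa in range(1, 200)}
        survivors = simkit.simulate_selection(
            events, tol, cargo_len=300, n_colonies=600,
            cds=cds, plasmid_len=len(small_plasmid), seed=3)
        aas = [cds.offset_of(s.position, len(small_plasmid)) // 3 + 1
               for s in survivors]
        frac_low = np.mean([aa <= 100 for aa in aas])
        # expected 0.9 / (0.9 + 0.1) = 0.9 if residues are evenly hit
        assert abs(frac_low - 0.9) < 0.08


class TestReads:
    def test_error_free_reads_are_substrings(self):
        rng = np.random.default_rng(0)
        t = simkit.random_dna(rng, 500)
        reads = simkit.simulate_reads(t, 50, read_len=100, error_rate=0.0,
                                      circular=True, seed=4)
        assert len(reads) == 50
        doubled = t + t
        assert all(r.seq in doubled for r in reads)

    def test_error_rate_recovered(self):
        rng = np.random.default_rng(1)
        t = simkit.random_dna(rng, 100)
        n, rl, er = 2000, 100, 0.01
        reads = simkit.simulate_reads(t, n, read_len=rl, error_rate=er,
                                      circular=False, seed=6)
        mism = sum(a != b for r in reads for a, b in zip(r.seq, t))
        total = n * rl
        sd = np.sqrt(total * er * (1 - er))
        assert abs(mism - total * er) < 3 * sd

    def test_errors_marked_low_quality(self):
        rng = np.random.default_rng(2)
        t = simkit.random_dna(rng, 100)
        reads = simkit.simulate_reads(t, 200, read_len=100, error_rate=0.02,
                                      circular=False, seed=7)
        for r in reads:
            for base, tb, q in zip(r.seq, t, r.quals):
                assert (base == tb) == (q == simkit.Q_CORRECT)

    def test_paired_mates_bracket_fragment(self):
        rng = np.random.default_rng(3)
        t = simkit.random_dna(rng, 400)
        reads = simkit.simulate_reads(t, 10, read_len=80, paired=True,
                                      insert_size=200, error_rate=0.0,
                                      circular=False, seed=8)
        assert len(reads) == 20
        for r1, r2 in zip(reads[::2], reads[1::2]):
            i = t.find(r1.seq)
            assert i >= 0
            frag = t[i:i + 200]
            assert reverse_complement(r2.seq) == frag[-80:]

    def test_short_template_rejected(self):
        with pytest.raises(ValueError):
            simkit.simulate_reads("ACGT" * 10, 5, read_len=100, circular=False)


class TestCallerOutputs:
    def test_perfect_sensitivity_recovers_truth(self):
        truth = simkit.make_true_snvs(50, genome_len=10**6, seed=1)
        out = simkit.simulate_caller_outputs(
            truth, genome_len=10**6, sensitivity=(1, 1, 1), fp_rate=(0, 0, 0),
            n_germline=10, seed=2)
        truth_keys = {v.key for v in truth}
        germ_keys = {v.key for v in out.germline}
        for name in out.caller_names:
            assert {v.key for v in out.edited[name]} == truth_keys | germ_keys
            assert {v.key for v in out.control[name]} == germ_keys

    def test_intersection_size_matches_product_of_sensitivities(self):
        n, s = 400, 0.8
        sizes = []
        for seed in range(10):
            truth = simkit.make_true_snvs(n, genome_len=10**8, seed=seed)
            out = simkit.simulate_caller_outputs(
                truth, genome_len=10**8, sensitivity=(s, s, s),
                fp_rate=(0, 0, 0), n_germline=0, seed=seed + 100)
            keys = [set(v.key for v in out.edited[c]) for c in out.caller_names]
            sizes.append(len(keys[0] & keys[1] & keys[2]))
        expected = n * s ** 3
        sd = np.sqrt(n * s ** 3 * (1 - s ** 3) / len(sizes))
        assert abs(np.mean(sizes) - expected) < 3 * sd

    def test_signature_proportion(self):
        truth = simkit.make_true_snvs(2000, genome_len=10**8, seed=4,
                                      p_cg_ta=0.92)
        frac = np.mean([(v.ref, v.alt) in {("C", "T"), ("G", "A")}
                        for v in truth])
        assert abs(frac - 0.92) < 3 * np.sqrt(0.92 * 0.08 / 2000)


def test_truth_json_roundtrip(tmp_path, small_plasmid, cargo):
    _, truth = simkit.simulate_insertion_library(small_plasmid, cargo, n=5,
                                                 seed=9)
    truth.true_snvs = simkit.make_true_snvs(3, genome_len=1000, seed=9)
    truth.true_edit_rates = {5: 0.5}
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = simkit.SyntheticTruth.from_json(p)
    assert back == truth
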