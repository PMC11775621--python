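import math

import numpy as np
import pytest

import telomark as tm
from telomark.inserts import InsertEvent
from conftest import random_dna
from helpers_oracles import brute_duplication_length


@pytest.fixture(scope="module")
def cargo():
    return tm.CargoSpec()


def _read_with_insert(rng, host_len=2000, d=0, reverse=False, cargo_seq=tm.CARGO_SENSE):
    host = random_dna(rng, host_len)
    p = int(rng.integers(200, host_len - 200))
    insert = tm.revcomp(cargo_seq) if reverse else cargo_seq
    dup = host[p - d : p] if d else ""
    return host[:p] + insert + dup + host[p:], p


class TestFindInserts:
    def test_exact_forward_insert(self, cargo):
        rng = np.random.default_rng(0)
        read, p = _read_with_insert(rng)
        events = tm.find_inserts(read, cargo)
        assert len(events) == 1
        ev = events[0]
        assert (ev.insert_start, ev.insert_end, ev.orientation) == (p, p + 95, "forward")
        assert ev.mismatches == 0

    def test_no_cargo_no_events(self, cargo):
        rng = np.random.default_rng(1)
        assert tm.find_inserts(random_dna(rng, 1500), cargo) == []

    def test_reverse_complement_insert(self, cargo):
        rng = np.random.default_rng(2)
        read, p = _read_with_insert(rng, reverse=True)
        events = tm.find_inserts(read, cargo)
        assert len(events) == 1
        assert (events[0].insert_start, events[0].orientation) == (p, "reverse")

    def test_two_inserts_in_one_read(self, cargo):
        rng = np.random.default_rng(3)
        host = random_dna(rng, 3000)
        read = host[:500] + tm.CARGO_SENSE + host[500:2000] + tm.revcomp(tm.CARGO_SENSE) + host[2000:]
        events = tm.find_inserts(read, cargo)
        assert [(e.insert_start, e.orientation) for e in events] == [
            (500, "forward"),
            (2095, "reverse"),
        ]

    def test_recall_under_substitution_noise(self, cargo):
        """Recall >= 0.95 with 5% uniform substitution over the whole read."""
        rng = np.random.default_rng(44)
        found = 0
        n = 200
        for _ in range(n):
            read, p = _read_with_insert(rng, host_len=1000)
            chars = list(read)
            for i in np.flatnonzero(rng.random(len(chars)) < 0.05):
                chars[i] = "ACGT"[int(rng.integers(0, 4))]
            events = tm.find_inserts("".join(chars), cargo)
            found += any(ev.insert_start == p for ev in events)
        assert found / n >= 0.95

    def test_mismatch_free_recall_and_position_exact(self, cargo):
        rng = np.random.default_rng(45)
        for _ in range(50):
            read, p = _read_with_insert(rng, host_len=800)
            events = tm.find_inserts(read, cargo)
            assert len(events) == 1 and events[0].insert_start == p


class TestDuplicationLength:
    def test_nine_bp_duplication(self, cargo):
        rng = np.random.default_rng(10)
        read, _ = _read_with_insert(rng, d=9)
        (ev,) = tm.find_inserts(read, cargo)
        assert tm.duplication_length(ev) == 9

    def test_disjoint_alphabet_flanks_give_zero(self):
        ev = InsertEvent("r", 30, 125, "forward", left_flank="A" * 30, right_flank="C" * 30)
        assert tm.duplication_length(ev) == 0

    def test_matches_bruteforce_oracle_for_constructed_d(self, cargo):
        """Constructed duplications d in 0..12 across random hosts equal the loop-over-d oracle."""
        rng = np.random.default_rng(11)
        for trial in range(200):
            d = trial % 13
            read, _ = _read_with_insert(rng, host_len=600, d=d)
            (ev,) = tm.find_inserts(read, cargo)
            measured = tm.duplication_length(ev)
            assert measured == brute_duplication_length(ev.left_flank, ev.right_flank)
            assert measured >= d  # chance flank matches can only lengthen

    def test_short_flank_rejected(self):
        ev = InsertEvent("r", 5, 100, "forward", left_flank="ACGTA", right_flank="A" * 30)
        with pytest.raises(ValueError):
            tm.duplication_length(ev)


class TestContextMatrix:
    def test_identical_hosts_give_unit_columns(self, cargo):
        rng = np.random.default_rng(20)
        host = random_dna(rng, 400)
        p = 200
        read = host[:p] + tm.CARGO_SENSE + host[p:]
        reads = {f"r{i}": read for i in range(5)}
        events = []
        for rid in reads:
            events.extend(tm.find_inserts(reads[rid], cargo, read_id=rid))
        mat = tm.insertion_context_matrix(events, reads, window=20).frequencies
        assert (mat.max(axis=1) == 1.0).all()
        assert len(mat) == 40

    def test_reverse_events_stacked_in_cargo_frame(self, cargo):
        rng = np.random.default_rng(21)
        host = random_dna(rng, 400)
        p = 200
        fwd_read = host[:p] + tm.CARGO_SENSE + host[p:]
        rc_read = tm.revcomp(fwd_read)
        reads = {"fwd": fwd_read, "rev": rc_read}
        events = []
        for rid, seq in reads.items():
            events.extend(tm.find_inserts(seq, cargo, read_id=rid))
        mat = tm.insertion_context_matrix(events, reads, window=20).frequencies
        # same genomic context seen from both strands stacks identically
        assert (mat.max(axis=1) == 1.0).all()

    def test_no_usable_events_is_error(self, cargo):
        rng = np.random.default_rng(22)
        read = tm.CARGO_SENSE + random_dna(rng, 200)  # insert at the very start
        events = tm.find_inserts(read, cargo)
        with pytest.raises(ValueError):
            tm.insertion_context_matrix(events, {"": read}, window=20)


class TestProximityHistogram:
    def test_insertions_at_motif_boundary(self, cargo):
        rng = np.random.default_rng(30)
        reads = {}
        events = []
        for i in range(10):
            host = random_dna(rng, 300) + "TTAGGG" * 5 + random_dna(rng, 300)
            p = 300  # exactly at the first TTAGGG start
            read = host[:p] + tm.CARGO_SENSE + host[p:]
            rid = f"r{i}"
            reads[rid] = read
            events.extend(tm.find_inserts(read, cargo, read_id=rid))
        hist = tm.telomere_proximity_histogram(events, reads)
        assert hist == {0: 10}

    def test_no_motif_anywhere(self, cargo):
        rng = np.random.default_rng(31)
        host = "".join("AC"[i] for i in rng.integers(0, 2, 600))  # AC-only, no TTAGGG
        read = host[:300] + tm.CARGO_SENSE + host[300:]
        events = tm.find_inserts(read, cargo)
        assert tm.telomere_proximity_histogram(events, {"": read}) == {}

    def test_offsets_within_range(self, cargo):
        rng = np.random.default_rng(32)
        reads, events = {}, []
        for i in range(30):
            read, _ = _read_with_insert(rng, host_len=1000)
            rid = f"r{i}"
            reads[rid] = read
            events.extend(tm.find_inserts(read, cargo, read_id=rid))
        hist = tm.telomere_proximity_histogram(events, reads, search_range=60)
        assert all(-60 <= off <= 60 for off in hist)


class TestNtaByInsertStatus:
    def test_no_cargo_gives_undefined_insert_nta(self, cargo):
        rng = np.random.default_rng(40)
        reads = [(f"r{i}", random_dna(rng, 500)) for i in range(5)]
        nta_all, nta_ins = tm.nta_by_insert_status(reads, cargo)
        assert nta_all == 0.0 and math.isnan(nta_ins)

    def test_motifs_only_inside_cargo_are_masked(self):
        # a cargo that itself carries a telomere-like run; the same rules apply
        sense = (
            tm.MOSAIC_END + "ACACACACACACACACACAC" + "TTAGGG" * 3
            + "GTGTGTGTGTGTGTGTGTG" + tm.MOSAIC_END
        )
        assert len(sense) == 95
        motif_cargo = tm.CargoSpec(sense_sequence=sense)
        rng = np.random.default_rng(41)
        host = "".join("AC"[i] for i in rng.integers(0, 2, 400))  # motif-free host
        read = host[:200] + sense + host[200:]
        nta_all, nta_ins = tm.nta_by_insert_status([("r", read)], motif_cargo)
        assert nta_all == 0.0 and nta_ins == 0.0

    def test_protected_telomere_lowers_insert_nta(self):
        """When the telomere proper receives no insertions, insert-bearing reads
        are depleted of telomere-like sequence relative to all reads."""
        spec = tm.SyntheticGenomeSpec(
            n_arms=1, telomere_repeats=2000, subtelomere_length=0,
            chromatin_length=30_000, centromere_monomers=0, seed=6,
        )
        genome = tm.make_genome(spec)
        state = tm.CondensationState(telomere_weight=0.0)
        reads, truth = tm.simulate_longreads_with_inserts(
            genome, insertion_rate=1.5, duplication=0, n_reads=300,
            read_length=2000, placement_state=state, seed=7,
        )
        nta_all, nta_ins = tm.nta_by_insert_status(reads)
        assert nta_ins < nta_all
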