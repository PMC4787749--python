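"""Cross-hybridization screening: 5' rule, seed-based general rule,
pigeonhole guarantee, and agreement with the literal window-scan oracle."""

import numpy as np
import pytest

from primersweep import (
    CrossHybParams,
    FixtureSpec,
    SequenceDB,
    enumerate_candidates,
    generate_db,
    reverse_complement,
    seed_decompose,
)
from primersweep.crosshyb_filter import (
    brute_force_crosshyb,
    brute_force_general,
    five_prime_filter,
    general_filter,
    run_crosshyb,
)
from primersweep.single_filter import Primer, filter_candidates


def make_primer(seq, sid=0, start=10, direction="forward"):
    return Primer(
        primer_seq=seq, direction=direction,
        occurrences=[(sid, start, len(seq))], target_sids=frozenset({sid}),
        tm=60.0, gc=50.0, self_comp=0, end_self_comp=0, max_run=1, dg_3p=-5.0,
    )


def embed(primer_seq, flank_left, flank_right):
    return flank_left + primer_seq + flank_right


class TestSeedDecompose:
    def test_block_structure_m20_k2(self):
        keys = seed_decompose("ACGTACGTACGTACGTACGT", 2)
        assert [len(k.seed_seq) for k in keys] == [6, 6, 8]
        assert [k.block_offset for k in keys] == [0, 6, 12]

    def test_k0_is_whole_primer(self):
        (key,) = seed_decompose("ACGTAC", 0)
        assert key.seed_seq == "ACGTAC" and key.block_offset == 0

    @pytest.mark.parametrize("m,k", [(19, 3), (24, 4), (20, 2), (21, 1)])
    def test_blocks_partition_the_primer(self, m, k):
        rng = np.random.default_rng(m * 10 + k)
        seq = "".join(rng.choice(list("ACGT"), m))
        keys = seed_decompose(seq, k)
        assert "".join(k_.seed_seq for k_ in keys) == seq

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError):
            seed_decompose("ACG", 3)


class TestPigeonhole:
    def test_any_k_mismatch_window_shares_a_block(self):
        """A window within Hamming k of a primer always matches one of the
        k+1 blocks exactly at the same offset."""
        rng = np.random.default_rng(99)
        for _ in range(1500):
            m = int(rng.integers(15, 30))
            k = int(rng.integers(0, 5))
            primer = "".join(rng.choice(list("ACGT"), m))
            h = int(rng.integers(0, k + 1))
            window = list(primer)
            for pos in rng.choice(m, size=h, replace=False):
                window[pos] = rng.choice([b for b in "ACGT" if b != window[pos]])
            window = "".join(window)
            shared = any(
                window[key.block_offset:key.block_offset + len(key.seed_seq)]
                == key.seed_seq
                for key in seed_decompose(primer, k)
            )
            assert shared


class TestFivePrimeRule:
    ZONE = CrossHybParams()  # zone 4, up to 4 mismatches, K = 2

    def _db_with_offtarget(self, primer_seq, offtarget_window):
        left = "TTTTATTTTATTTTATTTAT"
        right = "ATTTAATTTTATTTTATTTT"
        return SequenceDB.from_sequences([
            embed(primer_seq, left, right),
            embed(offtarget_window, right, left),
        ])

    def test_5prime_mismatches_only_eliminate(self):
        p = "GACGATCGATTACGATCGAC"
        w = "TTCGATCGATTACGATCGAC"  # differs at positions 0-1 only
        db = self._db_with_offtarget(p, w)
        primer = make_primer(p)
        assert five_prime_filter([primer], db, self.ZONE) == []

    def test_3prime_mismatch_blocks_the_rule(self):
        p = "GACGATCGATTACGATCGAC"
        w = p[:15] + "A" + p[16:]  # one mismatch in the 3' half
        assert w != p
        db = self._db_with_offtarget(p, w)
        primer = make_primer(p)
        assert five_prime_filter([primer], db, self.ZONE) == [primer]

    def test_exact_second_occurrence_is_a_target_not_offtarget(self):
        p = "GACGATCGATTACGATCGAC"
        db = self._db_with_offtarget(p, p)  # exact copy in sequence 1
        primer = make_primer(p)
        survivors = five_prime_filter([primer], db, self.ZONE)
        assert survivors == [primer]


class TestGeneralRule:
    def _setup(self, h, seed=0):
        rng = np.random.default_rng(seed)
        p = "GACGATCGATTACGATCGAC"
        mutated = list(p)
        for pos in rng.choice(np.arange(4, len(p)), size=h, replace=False):
            mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
        flank = "TTTTATTTTATTTTATTTAT"
        db = SequenceDB.from_sequences([
            embed(p, flank, flank[::-1]),
            embed("".join(mutated), flank[::-1], flank),
        ])
        return make_primer(p), db

    def test_distance_2_eliminated_at_k2(self):
        primer, db = self._setup(h=2)
        assert general_filter([primer], db, 2) == []
        assert brute_force_general([primer], db, 2) == []

    def test_distance_3_retained_at_k2(self):
        primer, db = self._setup(h=3)
        assert general_filter([primer], db, 2) == [primer]
        assert brute_force_general([primer], db, 2) == [primer]

    def test_antisense_plant_behaves_identically(self):
        rng = np.random.default_rng(5)
        p = "GACGATCGATTACGATCGAC"
        mutated = list(p)
        for pos in rng.choice(np.arange(4, len(p)), size=2, replace=False):
            mutated[pos] = rng.choice([b for b in "ACGT" if b != mutated[pos]])
        flank = "TTTTATTTTATTTTATTTAT"
        db = SequenceDB.from_sequences([
            embed(p, flank, flank[::-1]),
            embed(reverse_complement("".join(mutated)), flank[::-1], flank),
        ])
        primer = make_primer(p)
        assert general_filter([primer], db, 2) == []

    def test_k0_eliminates_nothing(self):
        primer, db = self._setup(h=1)
        assert general_filter([primer], db, 0) == [primer]


@pytest.fixture(scope="module")
def survivor_sets(bank, single_c, tp):
    """Single-filter survivors per bank database (inputs to the screen)."""
    out = {}
    for e in bank[:8]:
        db = e["db"]
        out[e["seed"]] = (
            db,
            filter_candidates(
                enumerate_candidates(db, single_c.min_len, single_c.max_len),
                single_c, tp,
            ),
        )
    return out


class TestSeedVsBruteForce:
    def test_full_screen_matches_oracle(self, survivor_sets, xh):
        for seed, (db, primers) in survivor_sets.items():
            seeded, _ = run_crosshyb(primers, db, xh)
            brute = brute_force_crosshyb(primers, db, xh)
            assert {p.key() for p in seeded} == {p.key() for p in brute}, seed

    def test_survivors_shrink_as_k_grows(self, survivor_sets, xh):
        for seed, (db, primers) in survivor_sets.items():
            prev = {p.key() for p in primers}
            for k in range(0, 4):
                cur = {p.key() for p in general_filter(primers, db, k)}
                assert cur <= prev
                prev = cur

    def test_iterative_schedule_equals_single_pass(self, survivor_sets):
        for seed, (db, primers) in survivor_sets.items():
            step = primers
            for k in (1, 2):
                step = general_filter(step, db, k)
            single = general_filter(primers, db, 2)
            assert {p.key() for p in step} == {p.key() for p in single}


class TestSingleSequenceDatabase:
    def test_no_offtargets_means_no_eliminations(self, single_c, tp, xh):
        rng = np.random.default_rng(77)
        db = SequenceDB.from_sequences(
            ["".join(rng.choice(list("ACGT"), 200))]
        )
        primers = filter_candidates(
            enumerate_candidates(db, single_c.min_len, single_c.max_len),
            single_c, tp,
        )
        survivors, _ = run_crosshyb(primers, db, xh)
        assert len(survivors) == len(primers)
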