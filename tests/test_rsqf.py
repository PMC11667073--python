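import warnings

import numpy as np
import pytest

from bqfilter.rsqf import RSQFilter, MAX_LOAD_FACTOR

from _oracles import global_runend_position, run_layout, runs_strictly_ascending


def make_filter(q=6, r=6, c=5):
    return RSQFilter(q, r, c)


def H(quotient, remainder, r=6):
    return (quotient << r) | remainder


class TestInsertAndQuery:
    def test_empty_filter_answers_absent(self):
        f = make_filter()
        assert f.query(1234) is None
        assert f.n == 0 and f.load_factor() == 0.0

    def test_insert_places_remainder_in_home_slot(self):
        f = make_filter()
        f.insert(H(3, 9))
        assert f.occupieds.get(3) == 1
        assert f.runends.get(3) == 1
        assert int(f.remainders[3]) == 9
        assert f.query(H(3, 9)) == 1

    def test_colliding_quotient_keeps_remainders_ascending(self):
        f = make_filter()
        f.insert(H(5, 40))
        f.insert(H(5, 7))  # smaller remainder arrives second
        layout = run_layout(f)
        assert [rm for rm, _ in layout[5]] == [7, 40]
        assert f.query(H(5, 7)) == 1 and f.query(H(5, 40)) == 1

    def test_duplicate_insert_merges_with_saturation(self):
        f = make_filter(c=5)
        f.insert(H(2, 1), 2)
        f.insert(H(2, 1), 3)
        assert f.query(H(2, 1)) == 5
        f.insert(H(2, 1), 100)
        assert f.query(H(2, 1)) == 31  # capped at 2**c - 1

    def test_large_count_saturates_at_counter_cap(self):
        f = make_filter(c=5)
        f.insert(H(0, 1), 100)
        assert f.query(H(0, 1)) == 31

    def test_count_below_one_rejected(self):
        with pytest.raises(ValueError):
            make_filter().insert(5, 0)

    def test_shifted_run_wraps_around_the_table_end(self):
        f = make_filter()
        # fill the tail so a run insert at the last quotient wraps to slot 0
        last = f.num_slots - 1
        for rem in range(1, 4):
            f.insert(H(last, rem))
        layout = run_layout(f)
        assert [rm for rm, _ in layout[last]] == [1, 2, 3]
        assert f.in_use.get(0) and f.in_use.get(1)
        for rem in range(1, 4):
            assert f.query(H(last, rem)) == 1
        assert f.query(H(0, 1)) is None  # slot 0 is used but quotient 0 is not


class TestOracleEquivalence:
    def test_randomized_ops_match_dictionary(self, rng):
        f = make_filter(q=6, r=8, c=5)
        oracle = {}
        cap = 31
        for step in range(3000):
            h = rng.randrange(1 << 14)
            u = rng.random()
            if u < 0.6:
                cnt = rng.randrange(1, 50)
                f.insert(h, cnt)
                oracle[h] = min(oracle.get(h, 0) + cnt, cap)
            elif u < 0.8 and oracle:
                victim = rng.choice(list(oracle))
                f.delete(victim)
                del oracle[victim]
            else:
                assert f.query(h) == oracle.get(h)
            if step % 500 == 0:
                assert dict(f.enumerate()) == oracle
                assert runs_strictly_ascending(f)
        assert dict(f.enumerate()) == oracle

    def test_exhaustive_small_universe_has_no_false_answers(self, rng):
        # every query over the full hash universe is exact
        f = make_filter(q=6, r=6, c=3)
        oracle = {}
        for _ in range(50):
            h = rng.randrange(1 << 12)
            f.insert(h)
            oracle[h] = min(oracle.get(h, 0) + 1, 7)
        for h in range(1 << 12):
            assert f.query(h) == oracle.get(h)


class TestRunendPosition:
    def test_simple_run_fixture(self):
        f = make_filter()
        for rem in (3, 5, 9):
            f.insert(H(8, rem))
        assert f.runend_position(8) == 10  # run occupies slots 8, 9, 10

    def test_three_singleton_runs_fixture(self):
        f = make_filter()
        for quot in (13, 14, 15):
            f.insert(H(quot, 1))
        assert f.runend_position(13) == 13
        assert f.runend_position(14) == 14
        assert f.runend_position(15) == 15

    def test_unoccupied_quotient_returns_sentinel(self):
        f = make_filter()
        assert f.runend_position(8) is None

    @pytest.mark.parametrize("q", [6, 7, 8])
    def test_block_formula_equals_global_formula(self, rng, q):
        for trial in range(20):
            r = 12 - q
            f = RSQFilter(q, r, 3)
            n = rng.randrange(0, int(0.9 * f.num_slots))
            for _ in range(n):
                f.insert(rng.randrange(1 << 12))
            for x in range(f.num_slots):
                assert f.runend_position(x) == global_runend_position(f, x)


class TestDelete:
    def test_insert_then_delete_is_absent(self):
        f = make_filter()
        f.insert(H(4, 2))
        f.delete(H(4, 2))
        assert f.query(H(4, 2)) is None
        assert f.n == 0

    def test_delete_middle_of_run_keeps_order(self):
        f = make_filter()
        for rem in (2, 5, 8):
            f.insert(H(9, rem))
        f.delete(H(9, 5))
        layout = run_layout(f)
        assert [rm for rm, _ in layout[9]] == [2, 8]
        assert f.query(H(9, 2)) == 1 and f.query(H(9, 8)) == 1
        assert f.query(H(9, 5)) is None

    def test_delete_absent_warns_and_preserves_state(self):
        f = make_filter()
        f.insert(H(1, 1))
        before = dict(f.enumerate())
        with pytest.warns(UserWarning):
            f.delete(H(1, 2))
        assert dict(f.enumerate()) == before

    def test_delete_on_empty_filter_warns(self):
        f = make_filter()
        with pytest.warns(UserWarning):
            f.delete(123)
        assert f.n == 0


class TestResize:
    def test_resize_of_empty_filter(self):
        f = make_filter(q=6, r=6)
        f.resize()
        assert f.q == 7 and f.r == 5 and f.n == 0
        assert f.num_slots == 128

    def test_resize_preserves_every_query(self, rng):
        f = make_filter(q=7, r=9, c=5)
        oracle = {}
        for _ in range(100):
            h = rng.randrange(1 << 16)
            cnt = rng.randrange(1, 60)
            f.insert(h, cnt)
            oracle[h] = min(oracle.get(h, 0) + cnt, 31)
        before = sorted(f.enumerate())
        f.resize()
        assert f.q == 8 and f.r == 8
        assert sorted(f.enumerate()) == before
        for h, cnt in oracle.items():
            assert f.query(h) == cnt

    def test_load_factor_halves_on_resize(self, rng):
        f = make_filter(q=6, r=10)
        seen = set()
        while len(seen) < 32:
            h = rng.randrange(1 << 16)
            if h not in seen:
                f.insert(h)
                seen.add(h)
        assert f.load_factor() == 0.5
        f.resize()
        assert f.load_factor() == 0.25

    def test_resize_without_remainder_bits_fails(self):
        f = make_filter(q=6, r=0)
        with pytest.raises(ValueError):
            f.resize()

    def test_automatic_resize_keeps_load_below_threshold(self, rng):
        f = make_filter(q=6, r=14, c=2)
        seen = set()
        for _ in range(500):
            h = rng.randrange(1 << 20)
            f.insert(h)
            seen.add(h)
            assert f.load_factor() <= MAX_LOAD_FACTOR + 1e-12
        assert f.n == len(seen)


class TestBulkConstruction:
    def test_bulk_build_equals_incremental_inserts(self, rng):
        q, r, c = 6, 6, 5
        hashes = sorted(rng.sample(range(1 << 12), 50))
        counts = [rng.randrange(1, 31) for _ in hashes]
        bulk = RSQFilter.from_sorted_hashes(
            q, r, c, np.array(hashes, dtype=np.uint64), np.array(counts, dtype=np.uint64)
        )
        inc = RSQFilter(q, r, c)
        for h, cnt in zip(hashes, counts):
            inc.insert(h, cnt)
        assert np.array_equal(bulk.remainders, inc.remainders)
        assert np.array_equal(bulk.counters, inc.counters)
        assert np.array_equal(bulk.occupieds.words, inc.occupieds.words)
        assert np.array_equal(bulk.runends.words, inc.runends.words)
        assert np.array_equal(bulk.offsets, inc.offsets)

    def test_bulk_build_handles_wrapping_tail(self, rng):
        # quotients packed at the top of the table force wrap-around clusters
        q, r, c = 6, 6, 5
        N = 1 << q
        hs = set()
        while len(hs) < 40:
            hs.add(((N - 1 - rng.randrange(4)) << r) | rng.randrange(1 << r))
        hashes = np.array(sorted(hs), dtype=np.uint64)
        counts = np.ones(hashes.size, dtype=np.uint64)
        bulk = RSQFilter.from_sorted_hashes(q, r, c, hashes, counts)
        inc = RSQFilter(q, r, c)
        for h in hashes.tolist():
            inc.insert(int(h))
        assert np.array_equal(bulk.remainders, inc.remainders)
        assert np.array_equal(bulk.offsets, inc.offsets)
        assert dict(bulk.enumerate()) == {int(h): 1 for h in hashes.tolist()}

    def test_rejects_unsorted_hashes(self):
        with pytest.raises(ValueError):
            RSQFilter.from_sorted_hashes(
                6, 6, 5, np.array([5, 3], dtype=np.uint64), np.ones(2, dtype=np.uint64)
            )


class TestSizeAccounting:
    def test_size_formula_fixed_values(self):
        f = RSQFilter(10, 28, 5)  # s=19
        assert f.size_bits() == 36864
        f.resize()
        assert f.size_bits() == 2**11 * (27 + 5 + 3) == 71680

    def test_metadata_share_is_three_bits_per_slot(self):
        f = RSQFilter(8, 10, 5)
        assert f.size_bits() - f.num_slots * (f.r + f.c) == 3 * f.num_slots

    def test_offsets_one_per_64_slot_block(self):
        for q in (6, 8, 11):
            f = RSQFilter(q, 4, 2)
            assert f.offsets.size == (1 << q) // 64

    def test_load_factor_simple_values(self, rng):
        f = RSQFilter(7, 10, 2)
        seen = set()
        while len(seen) < 64:
            h = rng.randrange(1 << 17)
            if h not in seen:
                f.insert(h)
                seen.add(h)
        assert f.load_factor() == 0.5


class TestSerializationSupport:
    def test_rebuild_in_use_matches_maintained_bitvector(self, rng):
        f = RSQFilter(6, 8, 4)
        for _ in range(50):
            f.insert(rng.randrange(1 << 14))
        maintained = f.in_use.to_bool_array()
        f.rebuild_in_use()
        assert np.array_equal(f.in_use.to_bool_array(), maintained)
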