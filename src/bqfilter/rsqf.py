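"""Rank-and-select quotient filter with per-slot abundance counters.

The filter is a circular table of ``2**q`` slots.  An element's 2s-bit hash
is split into a quotient (the top ``q`` bits, its home address) and a
remainder (the low ``r = 2s - q`` bits, which is what the slot stores),
together with a ``c``-bit saturating counter.  Elements whose hashes share a
quotient form a *run* of consecutive slots holding remainders in strictly
ascending order; runs pushed out of their home slot by earlier runs are
located through two metadata bit vectors (``occupieds``, ``runends``) via
rank/select, accelerated by one 64-bit offset checkpoint per 64-slot block.

Because the hash is a bijection, a (quotient, remainder) pair identifies the
original s-mer exactly: lookups have no false positives or negatives at the
s-mer level, stored elements can be enumerated, and the table can be doubled
in place (one remainder bit promotes into the quotient) when the load factor
would exceed 95 %.

Total size is ``2**q * (r + c + 3)`` bits: r remainder + c counter + 3
metadata bits per slot (occupied, runend, and the amortized 64-bit offset).
"""

from __future__ import annotations

import bisect
import warnings
from collections import deque
from typing import Iterator, Optional

import numpy as np

from .bitops import PackedBits

__all__ = ["RSQFilter", "MAX_LOAD_FACTOR", "MIN_Q"]

#: Doubling fires when an insert would push n / 2**q beyond this.
MAX_LOAD_FACTOR = 0.95

#: Block machinery needs at least one full 64-slot block.
MIN_Q = 6


class RSQFilter:
    """Quotient filter storing ``r``-bit remainders with ``c``-bit counters.

    Parameters
    ----------
    q : int
        Address bits; the table has ``2**q`` slots (q >= 6).
    r : int
        Remainder bits per slot (q + r = 2s is fixed across resizes).
    c : int
        Counter bits per slot; counts saturate at ``2**c - 1``.
    """

    def __init__(self, q: int, r: int, c: int):
        if q < MIN_Q:
            raise ValueError(f"q must be >= {MIN_Q} (need at least one 64-slot block)")
        if r < 0:
            raise ValueError("r must be >= 0")
        if c < 1:
            raise ValueError("c must be >= 1")
        self.q = q
        self.r = r
        self.c = c
        self.n = 0
        N = 1 << q
        self.num_slots = N
        self.remainders = np.zeros(N, dtype=np.uint64)
        self.counters = np.zeros(N, dtype=np.uint64)
        self.occupieds = PackedBits(N)
        self.runends = PackedBits(N)
        self.offsets = np.zeros(N >> 6, dtype=np.int64)
        # Derived acceleration bitvector (which slots hold a record); not part
        # of the structure's accounting and reconstructible from the metadata.
        self.in_use = PackedBits(N)

    # -- basic accounting ---------------------------------------------------

    @property
    def counter_cap(self) -> int:
        return (1 << self.c) - 1

    def load_factor(self) -> float:
        """Stored elements divided by slot count."""
        return self.n / self.num_slots

    def size_bits(self) -> int:
        """Structure size: ``2**q * (r + c + 3)`` bits.

        Per slot: r remainder bits, c counter bits, occupied + runend bits,
        and one 64-bit offset per 64-slot block (1 amortized bit).
        """
        return self.num_slots * (self.r + self.c + 3)

    # -- rank/select machinery ----------------------------------------------

    def _select_runends_from(self, pos: int, count: int) -> int:
        """Position of the ``count``-th set runend bit at index >= pos, circular."""
        words = self.runends.words
        nw = words.size
        j, t = pos >> 6, pos & 63
        w = int(words[j]) & ~((1 << t) - 1)
        seen = 0
        for _ in range(2 * nw + 2):
            pc = w.bit_count()
            if seen + pc >= count:
                need = count - seen
                while need > 1:
                    w &= w - 1
                    need -= 1
                return ((j << 6) + ((w & -w).bit_length() - 1)) % self.num_slots
            seen += pc
            j = (j + 1) % nw
            w = int(words[j])
        raise RuntimeError("corrupt filter: runend select ran past the table")

    def _run_end_general(self, x: int) -> tuple[Optional[int], bool]:
        """Runend of the last run with quotient (circularly) at or before ``x``.

        Returns ``(end, free)`` where ``free`` is True when slot ``x`` is not
        covered by any run (so a new element with quotient ``x`` would land in
        its home slot).  Uses only occupieds/runends/offsets.
        """
        N = self.num_slots
        b = x >> 6
        B = b << 6
        within = x - B
        occw = int(self.occupieds.words[b])
        d = (occw & ((1 << (within + 1)) - 1)).bit_count()
        O = int(self.offsets[b])
        occupied_B = occw & 1
        dd = d - 1 if occupied_B else d
        active = bool(O > 0 or occupied_B or self.runends.get(B))
        if dd <= 0:
            if not active:
                return None, True
            e = (B + O) % N
            free = ((e - B) % N) < within if not (occupied_B and within == 0) else False
            # occupied home slot x == B: its run ends at e, never free
            if occupied_B and within == 0:
                return e, False
            return e, free
        start = (B + O + 1) % N if active else B
        e = self._select_runends_from(start, dd)
        free = ((e - B) % N) < within
        return e, free

    def _run_end(self, x: int) -> int:
        """Runend slot of the run whose quotient is ``x`` (requires occupied(x))."""
        e, _free = self._run_end_general(x)
        if e is None:
            raise RuntimeError("corrupt filter: occupied quotient without a run")
        return e

    def runend_position(self, i: int) -> Optional[int]:
        """Slot holding the last remainder of quotient ``i``'s run, or None.

        Block-accelerated: identical to the global formula
        ``select(runends, rank(occupieds, i))`` evaluated in a frame unrolled
        at an empty slot.
        """
        if not 0 <= i < self.num_slots:
            raise IndexError(f"slot index {i} out of range")
        if not self.occupieds.get(i):
            return None
        return self._run_end(i)

    # -- queries -------------------------------------------------------------

    def _split(self, h: int) -> tuple[int, int]:
        return h >> self.r, h & ((1 << self.r) - 1)

    def query(self, h: int) -> Optional[int]:
        """Stored counter for hash ``h``, or None if absent (always exact)."""
        x, rem = self._split(h)
        if not self.occupieds.get(x):
            return None
        N = self.num_slots
        p = self._run_end(x)
        runends = self.runends
        in_use = self.in_use
        remainders = self.remainders
        while True:
            rp = int(remainders[p])
            if rp == rem:
                return int(self.counters[p])
            if rp < rem or p == x:
                return None
            p1 = (p - 1) % N
            if runends.get(p1) or not in_use.get(p1):
                return None
            p = p1

    def query_many(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized batch query.

        Returns ``(present, counts)``; counts are 0 where absent.  The
        occupied-bit test is vectorized; only hashes whose home slot is
        occupied fall through to the per-run scan.
        """
        hashes = np.asarray(hashes, dtype=np.uint64)
        quotients = (hashes >> np.uint64(self.r)).astype(np.int64)
        occ = (self.occupieds.words[quotients >> 6] >> (quotients.astype(np.uint64) & np.uint64(63))) & np.uint64(1)
        present = np.zeros(hashes.size, dtype=bool)
        counts = np.zeros(hashes.size, dtype=np.uint64)
        candidates = np.flatnonzero(occ)
        query = self.query
        for i in candidates:
            res = query(int(hashes[i]))
            if res is not None:
                present[i] = True
                counts[i] = res
        return present, counts

    # -- cluster decoding / canonical placement ------------------------------

    def _scan_back_empty(self, x: int) -> int:
        """Largest slot z at or before ``x`` (circularly) with no record."""
        N = self.num_slots
        words = self.in_use.words
        nw = words.size
        j, t = x >> 6, x & 63
        w = (~int(words[j])) & ((1 << (t + 1)) - 1)
        for _ in range(nw + 1):
            if w:
                return ((j << 6) + (w.bit_length() - 1)) % N
            j = (j - 1) % nw
            w = (~int(words[j])) & ((1 << 64) - 1)
        raise RuntimeError("filter has no empty slot")

    def _decode_region(self, start: int) -> tuple[list[tuple[int, list[tuple[int, int]]]], int]:
        """Decode the contiguous in-use region beginning at ``start``.

        ``start`` must be preceded by an empty slot.  Returns
        ``(runs, extent)`` where ``runs`` is a list of
        ``(quotient, [(remainder, counter), ...])`` in placement order and
        ``extent`` is the number of consecutive in-use slots consumed.
        """
        N = self.num_slots
        runs: list[tuple[int, list[tuple[int, int]]]] = []
        pending: deque[int] = deque()
        current: Optional[list[tuple[int, int]]] = None
        p = start
        extent = 0
        occ = self.occupieds
        rend = self.runends
        while extent <= N:
            if occ.get(p):
                pending.append(p)
            if current is None:
                if not pending:
                    break
                qx = pending.popleft()
                current = []
                runs.append((qx, current))
            current.append((int(self.remainders[p]), int(self.counters[p])))
            if rend.get(p):
                current = None
            p = (p + 1) % N
            extent += 1
        if extent > N:
            raise RuntimeError("corrupt filter: unterminated cluster")
        return runs, extent

    def _write_region(
        self,
        start: int,
        old_extent: int,
        runs: list[tuple[int, list[tuple[int, int]]]],
    ) -> None:
        """Greedily re-place ``runs`` over the region starting at ``start``.

        Slots of the old extent not reused are cleared.  Offsets of every
        block whose leading slot falls inside the touched region are
        recomputed from the placed layout.
        """
        N = self.num_slots
        placed: list[tuple[int, int, int, bool]] = []  # (slot, remainder, counter, is_end)
        run_spans: list[tuple[int, int]] = []  # (uq, end_un) in unrolled coords
        pos_un = 0
        for qx, items in runs:
            uq = (qx - start) % N
            s_un = max(uq, pos_un)
            for idx, (rem, cnt) in enumerate(items):
                placed.append(((start + s_un + idx) % N, rem, cnt, idx == len(items) - 1))
            pos_un = s_un + len(items)
            run_spans.append((uq, pos_un - 1))
        new_extent = pos_un
        if new_extent > N:
            raise RuntimeError("region overflow during rebuild")
        touched = max(old_extent, new_extent)
        # clear the touched region, then write the placement
        for t in range(touched):
            p = (start + t) % N
            self.remainders[p] = 0
            self.counters[p] = 0
            self.runends.clear(p)
            self.in_use.clear(p)
        for p, rem, cnt, is_end in placed:
            self.remainders[p] = rem
            self.counters[p] = cnt
            self.in_use.set(p)
            if is_end:
                self.runends.set(p)
        # recompute offsets for blocks leading inside the touched region
        uqs = [sp[0] for sp in run_spans]
        ends = [sp[1] for sp in run_spans]
        B = (((start + 63) >> 6) << 6) % N  # first block-leading slot at or after start
        B_un = (B - start) % N
        while B_un < touched:
            idx = bisect.bisect_right(uqs, B_un) - 1 if uqs else -1
            if idx < 0:
                self.offsets[B >> 6] = 0
            else:
                e_un = ends[idx]
                self.offsets[B >> 6] = e_un - B_un if e_un >= B_un else 0
            B = (B + 64) % N
            B_un += 64

    # -- mutation ------------------------------------------------------------

    def insert(self, h: int, count: int = 1) -> "RSQFilter":
        """Insert hash ``h`` with abundance ``count`` (saturating merge).

        A duplicate (quotient, remainder) pair has its counter increased by
        ``count``, saturating at ``2**c - 1``.  If the pre-insert load factor
        would exceed 95 %, the table is doubled first.
        """
        if count < 1:
            raise ValueError("insert count must be >= 1")
        if (self.n + 1) / self.num_slots > MAX_LOAD_FACTOR:
            self.resize()
        x, rem = self._split(h)
        cap = self.counter_cap
        # duplicate: bump the counter in place, no layout change
        if self.occupieds.get(x):
            pos = self._find_slot(x, rem)
            if pos is not None:
                self.counters[pos] = min(int(self.counters[pos]) + count, cap)
                return self
        stored = min(count, cap)
        if not self.in_use.get(x):
            # home slot is free: trivial placement
            self.remainders[x] = rem
            self.counters[x] = stored
            self.occupieds.set(x)
            self.runends.set(x)
            self.in_use.set(x)
            # block offset of x's own block is unaffected (0 stays 0 when
            # x is block-leading: its run ends in its home slot)
            self.n += 1
            return self
        z = self._scan_back_empty(x)
        start = (z + 1) % self.num_slots
        runs, extent = self._decode_region(start)
        uq_new = (x - start) % self.num_slots
        placed_in = False
        for qx, items in runs:
            if qx == x:
                keys = [it[0] for it in items]
                items.insert(bisect.bisect_left(keys, rem), (rem, stored))
                placed_in = True
                break
        if not placed_in:
            uqs = [(qx - start) % self.num_slots for qx, _ in runs]
            runs.insert(bisect.bisect_left(uqs, uq_new), (x, [(rem, stored)]))
        self._write_region(start, extent, runs)
        self.occupieds.set(x)
        self.n += 1
        return self

    def _find_slot(self, x: int, rem: int) -> Optional[int]:
        """Slot index holding (quotient x, remainder rem), or None."""
        N = self.num_slots
        p = self._run_end(x)
        while True:
            rp = int(self.remainders[p])
            if rp == rem:
                return p
            if rp < rem or p == x:
                return None
            p1 = (p - 1) % N
            if self.runends.get(p1) or not self.in_use.get(p1):
                return None
            p = p1

    def delete(self, h: int) -> "RSQFilter":
        """Remove hash ``h``; absent elements warn and leave the state unchanged."""
        x, rem = self._split(h)
        if not self.occupieds.get(x) or self._find_slot(x, rem) is None:
            warnings.warn("delete of absent element ignored", stacklevel=2)
            return self
        z = self._scan_back_empty(x)
        start = (z + 1) % self.num_slots
        runs, extent = self._decode_region(start)
        new_runs = []
        for qx, items in runs:
            if qx == x:
                items = [it for it in items if it[0] != rem]
                if not items:
                    self.occupieds.clear(x)
                    continue
            new_runs.append((qx, items))
        self._write_region(start, extent, new_runs)
        self.n -= 1
        return self

    # -- enumeration / resize -------------------------------------------------

    def enumerate(self) -> Iterator[tuple[int, int]]:
        """Yield every stored ``(hash, counter)`` exactly once, hash-ascending."""
        N = self.num_slots
        r = self.r
        for b, w in enumerate(self.occupieds.words):
            w = int(w)
            while w:
                x = (b << 6) + ((w & -w).bit_length() - 1)
                w &= w - 1
                e = self._run_end(x)
                # collect the run back-to-front, then reverse
                items = []
                p = e
                while True:
                    items.append((int(self.remainders[p]), int(self.counters[p])))
                    if p == x:
                        break
                    p1 = (p - 1) % N
                    if self.runends.get(p1) or not self.in_use.get(p1):
                        break
                    p = p1
                for rem, cnt in reversed(items):
                    yield (x << r) | rem, cnt

    def resize(self) -> "RSQFilter":
        """Double the slot count: q+1 address bits, r-1 remainder bits.

        Every element keeps its 2s-bit hash; the split point moves by one
        bit, so counters and contents are preserved exactly and the load
        factor halves.
        """
        if self.r < 1:
            raise ValueError("cannot resize: no remainder bit left to promote")
        pairs = list(self.enumerate())
        if pairs:
            hashes = np.array([p[0] for p in pairs], dtype=np.uint64)
            counts = np.array([p[1] for p in pairs], dtype=np.uint64)
        else:
            hashes = np.empty(0, dtype=np.uint64)
            counts = np.empty(0, dtype=np.uint64)
        fresh = RSQFilter.from_sorted_hashes(self.q + 1, self.r - 1, self.c, hashes, counts)
        self.q = fresh.q
        self.r = fresh.r
        self.num_slots = fresh.num_slots
        self.n = fresh.n
        self.remainders = fresh.remainders
        self.counters = fresh.counters
        self.occupieds = fresh.occupieds
        self.runends = fresh.runends
        self.offsets = fresh.offsets
        self.in_use = fresh.in_use
        return self

    # -- bulk construction -----------------------------------------------------

    @classmethod
    def from_sorted_hashes(
        cls,
        q: int,
        r: int,
        c: int,
        hashes: np.ndarray,
        counts: np.ndarray,
    ) -> "RSQFilter":
        """Linear-time construction from distinct hash values in ascending order.

        Counts are stored saturated at ``2**c - 1``.  This is the fast path
        used when building from a counted dump and when resizing; the
        resulting layout is identical to inserting one element at a time.
        """
        self = cls(q, r, c)
        n = int(np.asarray(hashes).size)
        if n == 0:
            return self
        N = self.num_slots
        if n >= N:
            raise ValueError(f"{n} elements cannot fit in {N} slots")
        hashes = np.asarray(hashes, dtype=np.uint64)
        counts = np.asarray(counts, dtype=np.uint64)
        if hashes.size > 1 and not np.all(hashes[1:] > hashes[:-1]):
            raise ValueError("hashes must be strictly ascending (distinct)")
        quotients = (hashes >> np.uint64(r)).astype(np.int64)
        xu, L = np.unique(quotients, return_counts=True)
        cumL = np.cumsum(L)
        prevcum = cumL - L  # elements placed before each run
        a = xu - prevcum
        base = -1
        for _ in range(N):  # converges in a couple of passes; n < N guarantees a fixpoint
            starts = prevcum + np.maximum(np.maximum.accumulate(a), base + 1)
            ends = starts + L - 1
            new_base = int(ends[-1]) - N
            if new_base == base or int(ends[-1]) < N:
                break
            base = new_base
        run_of = np.repeat(np.arange(xu.size), L)
        pos = (starts[run_of] + (np.arange(n) - prevcum[run_of])) % N
        self.remainders[pos] = hashes & np.uint64((1 << r) - 1)
        cap = np.uint64(self.counter_cap)
        self.counters[pos] = np.minimum(counts, cap)
        occ_bool = np.zeros(N, dtype=bool)
        occ_bool[xu] = True
        rend_bool = np.zeros(N, dtype=bool)
        rend_bool[ends % N] = True
        use_bool = np.zeros(N, dtype=bool)
        use_bool[pos] = True
        self.occupieds = PackedBits.from_bool_array(occ_bool)
        self.runends = PackedBits.from_bool_array(rend_bool)
        self.in_use = PackedBits.from_bool_array(use_bool)
        self.n = n
        self.offsets = _offsets_from_layout(occ_bool, rend_bool, use_bool)
        return self

    # -- reconstruction (deserialization support) ------------------------------

    def rebuild_in_use(self) -> None:
        """Recompute the in-use bitvector from occupieds/runends/offsets."""
        N = self.num_slots
        if self.n == 0:
            self.in_use = PackedBits(N)
            return
        # find one empty slot by hopping over clusters
        p = 0
        z = None
        for _ in range(N + 2):
            e, free = self._run_end_general(p)
            if free:
                z = p
                break
            p = (e + 1) % N
        if z is None:
            raise RuntimeError("corrupt filter: no empty slot found")
        use = PackedBits(N)
        pending: deque[int] = deque()
        inside = False
        p = (z + 1) % N
        for _ in range(N - 1):
            if self.occupieds.get(p):
                pending.append(p)
            if not inside and pending:
                pending.popleft()
                inside = True
            if inside:
                use.set(p)
                if self.runends.get(p):
                    inside = False
            p = (p + 1) % N
        self.in_use = use

    # -- debugging ---------------------------------------------------------------

    def check_invariants(self) -> None:
        """Raise AssertionError if structural invariants are violated."""
        assert self.occupieds.popcount() == self.runends.popcount()
        assert self.in_use.popcount() == self.n
        for b in range(self.offsets.size):
            assert self.offsets[b] >= 0


def _offsets_from_layout(occ_bool: np.ndarray, rend_bool: np.ndarray, use_bool: np.ndarray) -> np.ndarray:
    """Block offsets from a full boolean layout, via the global rank/select formula.

    The formula ``O_B = max(0, select(runends, rank(occupieds, B)) - B)`` is
    evaluated in a frame unrolled at an empty slot (the table is circular, so
    rank/select only make sense relative to a cluster-free anchor).
    """
    N = occ_bool.size
    empty = np.flatnonzero(~use_bool)
    if empty.size == 0:
        raise ValueError("layout has no empty slot")
    z = int(empty[0])
    shift = (z + 1) % N
    occ_un = np.roll(occ_bool, -shift)
    rend_un = np.roll(rend_bool, -shift)
    rank_occ = np.cumsum(occ_un)  # inclusive rank
    rend_pos = np.flatnonzero(rend_un)
    B = np.arange(0, N, 64)
    B_un = (B - shift) % N
    d = rank_occ[B_un]
    offsets = np.zeros(N >> 6, dtype=np.int64)
    has = d > 0
    e_un = np.zeros_like(B_un)
    e_un[has] = rend_pos[d[has] - 1]
    off = e_un - B_un
    offsets[has] = np.maximum(0, off[has])
    return offsets
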