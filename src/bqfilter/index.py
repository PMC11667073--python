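"""The user-facing k-mer abundance index.

A :class:`BQFIndex` stores the abundances of all *s*-mers of a dataset in a
rank-and-select quotient filter and answers queries about *k*-mers
(``s <= k``) as the minimum abundance over the ``k - s + 1`` constituent
s-mers; a k-mer is reported absent as soon as any of its s-mers is absent.
Indexing s-mers instead of k-mers saves ``2(k - s)`` bits per slot at the
cost of *construction false positives*: a k-mer absent from the data is
reported present when every one of its s-mers happens to occur somewhere.

Counters are saturating ``c``-bit values.  In ``exact`` mode the count
itself is stored (capped at ``2**c - 1``, reported as a lower bound when
capped); in ``log2`` mode ``floor(log2(count))`` is stored, trading count
precision for range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np

from . import hashing
from .rsqf import MAX_LOAD_FACTOR, MIN_Q, RSQFilter

__all__ = ["BQFIndex", "CountedRecord", "Abundance", "count_smers_from_reads", "choose_q"]

COUNTER_MODES = ("exact", "log2")


@dataclass(frozen=True)
class CountedRecord:
    """An (s-mer, count) pair as read from or written to a counted dump."""

    smer: str
    count: int


class Abundance(NamedTuple):
    """A decoded abundance answer.

    ``value`` is the estimate; ``saturated`` is True when the stored counter
    hit its cap, in which case ``value`` is a lower bound.
    """

    value: int
    saturated: bool


def choose_q(n_elements: int, s: int, default: int = 16) -> int:
    """Smallest q with ``n / 2**q <= 0.95`` (clamped to [MIN_Q, 2s - 1]).

    With an unknown element count (``n_elements`` <= 0) the CLI default is
    returned.
    """
    hard_max = 2 * s  # at q = 2s the hash is fully consumed by the address (r = 0)
    if n_elements <= 0:
        return min(max(default, MIN_Q), hard_max)
    q = MIN_Q
    while n_elements / (1 << q) > MAX_LOAD_FACTOR:
        q += 1
        if q > hard_max:
            raise ValueError(
                f"{n_elements} distinct s-mers cannot fit at 95% load with s={s}"
            )
    return q


def _encode_count(count: int, mode: str, cap: int) -> int:
    if mode == "exact":
        return min(count, cap)
    return min(int(math.floor(math.log2(count))), cap) if count > 1 else 0


def _decode_count(stored: int, mode: str, cap: int) -> Abundance:
    if mode == "exact":
        return Abundance(stored, stored == cap)
    return Abundance(1 << stored, stored == cap)


def count_smers_from_reads(
    reads: Iterable[str], s: int, canonical: bool = True
) -> Iterator[CountedRecord]:
    """Exact (canonical) s-mer multiplicities over a read set.

    Windows containing a non-ACGT character are skipped.  Records are
    yielded in encoded (canonical) s-mer order.
    """
    codes, counts = _count_codes(reads, s, canonical)
    for code, count in zip(codes.tolist(), counts.tolist()):
        yield CountedRecord(hashing.decode_smer(code, s), int(count))


def _count_codes(reads: Iterable[str], s: int, canonical: bool) -> tuple[np.ndarray, np.ndarray]:
    """Distinct (canonical) s-mer codes and their multiplicities, vectorized."""
    chunks = []
    for seq in reads:
        codes, valid = hashing.encode_windows(seq, s)
        chunks.append(codes[valid])
    if not chunks:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allcodes = np.concatenate(chunks)
    if canonical:
        allcodes = hashing.canonical_codes(allcodes, s)
    return np.unique(allcodes, return_counts=True)


class BQFIndex:
    """Backpack quotient filter index over the s-mers of one dataset.

    Build with :meth:`build_from_counts` (a counted s-mer stream, e.g. a KMC
    dump) or :meth:`build_from_reads`; query with :meth:`query_kmer` /
    :meth:`query_sequence`.
    """

    def __init__(
        self,
        filter: RSQFilter,
        k: int,
        s: int,
        canonical: bool = True,
        counter_mode: str = "exact",
    ):
        if s > k:
            raise ValueError(f"s ({s}) must be <= k ({k})")
        if counter_mode not in COUNTER_MODES:
            raise ValueError(f"counter_mode must be one of {COUNTER_MODES}")
        if filter.q + filter.r != 2 * s:
            raise ValueError("filter quotient+remainder bits must equal 2s")
        self.filter = filter
        self.k = k
        self.s = s
        self.canonical = canonical
        self.counter_mode = counter_mode

    # -- construction -------------------------------------------------------

    @classmethod
    def build_from_counts(
        cls,
        records: Iterable[CountedRecord],
        k: int,
        s: int,
        c: int = 5,
        canonical: bool = True,
        counter_mode: str = "exact",
        min_count: int = 1,
        q: Optional[int] = None,
    ) -> "BQFIndex":
        """Build from a stream of counted s-mers.

        Records below ``min_count`` are dropped (the published experiments
        keep k-mers seen at least twice).  Duplicate s-mers (e.g. a
        non-canonical dump loaded canonically) are merged with a warning.
        """
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        if c < 1:
            raise ValueError("c must be >= 1")
        merged: dict[int, int] = {}
        dup = 0
        for lineno, rec in enumerate(records, start=1):
            if len(rec.smer) != s:
                raise ValueError(
                    f"record {lineno}: s-mer {rec.smer!r} has length {len(rec.smer)}, expected {s}"
                )
            if rec.count < 1:
                raise ValueError(f"record {lineno}: count must be >= 1")
            smer = hashing.canonical(rec.smer) if canonical else rec.smer.upper()
            code = hashing.encode_smer(smer)
            if code in merged:
                dup += 1
            merged[code] = merged.get(code, 0) + rec.count
        if dup:
            warnings.warn(f"{dup} duplicate s-mer record(s) merged", stacklevel=2)
        codes = np.fromiter(merged.keys(), dtype=np.uint64, count=len(merged))
        counts = np.fromiter(merged.values(), dtype=np.uint64, count=len(merged))
        keep = counts >= min_count
        return cls._from_code_counts(codes[keep], counts[keep], k, s, c, canonical, counter_mode, q)

    @classmethod
    def build_from_reads(
        cls,
        reads: Iterable[str],
        k: int,
        s: int,
        c: int = 5,
        canonical: bool = True,
        counter_mode: str = "exact",
        min_count: int = 1,
        q: Optional[int] = None,
    ) -> "BQFIndex":
        """Count the s-mers of ``reads`` and build the index in one step."""
        codes, counts = _count_codes(reads, s, canonical)
        keep = counts >= min_count
        return cls._from_code_counts(codes[keep], counts[keep], k, s, c, canonical, counter_mode, q)

    @classmethod
    def _from_code_counts(cls, codes, counts, k, s, c, canonical, counter_mode, q):
        n = int(codes.size)
        q = choose_q(n, s) if q is None else q
        if q > 2 * s:
            raise ValueError(f"q ({q}) must be <= 2s ({2 * s})")
        r = 2 * s - q
        cap = (1 << c) - 1
        if n:
            counts = counts.astype(np.uint64, copy=False)
            if counter_mode == "exact":
                stored = np.minimum(counts, np.uint64(cap))
            else:
                stored = np.minimum(
                    np.floor(np.log2(counts.astype(np.float64))).astype(np.uint64),
                    np.uint64(cap),
                )
            hashes = hashing.hash_codes(codes.astype(np.uint64, copy=False), s)
            order = np.argsort(hashes)
            filt = RSQFilter.from_sorted_hashes(q, r, c, hashes[order], stored[order])
        else:
            filt = RSQFilter(q, r, c)
        return cls(filt, k=k, s=s, canonical=canonical, counter_mode=counter_mode)

    # -- queries ------------------------------------------------------------

    def _smer_hash(self, smer: str) -> int:
        if self.canonical:
            smer = hashing.canonical(smer)
        return hashing.hash_2s(hashing.encode_smer(smer), self.s)

    def query_smer(self, smer: str) -> Optional[Abundance]:
        """Abundance of a single s-mer (exact; no false answers)."""
        if len(smer) != self.s:
            raise ValueError(f"expected an s-mer of length {self.s}")
        try:
            h = self._smer_hash(smer)
        except ValueError:
            return None
        stored = self.filter.query(h)
        if stored is None:
            return None
        return _decode_count(stored, self.counter_mode, self.filter.counter_cap)

    def query_kmer(self, kmer: str) -> Optional[Abundance]:
        """Abundance of a k-mer: the minimum over its constituent s-mers.

        Returns None ("absent") if any s-mer is absent or the k-mer contains
        a non-ACGT character.
        """
        if len(kmer) != self.k:
            raise ValueError(f"expected a k-mer of length {self.k}")
        best: Optional[int] = None
        for i in range(self.k - self.s + 1):
            try:
                h = self._smer_hash(kmer[i : i + self.s])
            except ValueError:
                return None
            stored = self.filter.query(h)
            if stored is None:
                return None
            if best is None or stored < best:
                best = stored
        assert best is not None
        return _decode_count(best, self.counter_mode, self.filter.counter_cap)

    def query_sequence(self, seq: str) -> list[Optional[Abundance]]:
        """Per-window k-mer abundances along ``seq`` (sliding-window minimum).

        Each s-mer is queried once; the result equals calling
        :meth:`query_kmer` on every window.  Sequences shorter than k give
        an empty list.
        """
        if len(seq) < self.k:
            return []
        present, stored = self._smer_presence(seq)
        return self._windows_from_smers(present, stored)

    def _smer_presence(self, seq: str) -> tuple[np.ndarray, np.ndarray]:
        codes, valid = hashing.encode_windows(seq, self.s)
        if self.canonical:
            codes = hashing.canonical_codes(codes, self.s)
        hashes = hashing.hash_codes(codes, self.s)
        present, stored = self.filter.query_many(hashes)
        present &= valid
        return present, stored

    def _windows_from_smers(
        self, present: np.ndarray, stored: np.ndarray
    ) -> list[Optional[Abundance]]:
        z1 = self.k - self.s + 1
        win_present, win_min = _window_min(present, stored, z1)
        cap = self.filter.counter_cap
        out: list[Optional[Abundance]] = []
        for ok, v in zip(win_present.tolist(), win_min.tolist()):
            out.append(_decode_count(int(v), self.counter_mode, cap) if ok else None)
        return out

    # -- enumeration / stats -------------------------------------------------

    def enumerate_smers(self) -> Iterator[CountedRecord]:
        """Decode every stored element back to its s-mer string and counter."""
        for h, cnt in self.filter.enumerate():
            code = hashing.unhash_2s(h, self.s)
            yield CountedRecord(hashing.decode_smer(code, self.s), int(cnt))

    def stats(self) -> dict:
        f = self.filter
        d = {
            "k": self.k,
            "s": self.s,
            "q": f.q,
            "r": f.r,
            "c": f.c,
            "n": f.n,
            "canonical": self.canonical,
            "counter_mode": self.counter_mode,
            "load_factor": f.load_factor(),
            "size_bits": f.size_bits(),
            "size_bytes": f.size_bits() // 8,
        }
        d["bits_per_element"] = f.size_bits() / f.n if f.n else float("nan")
        return d


def _window_min(present: np.ndarray, stored: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """All-present flag and minimum of ``stored`` over sliding windows."""
    nwin = present.size - width + 1
    if nwin <= 0:
        return np.empty(0, dtype=bool), np.empty(0, dtype=np.uint64)
    cs = np.concatenate(([0], np.cumsum(present.astype(np.int64))))
    win_present = (cs[width:] - cs[:-width]) == width
    masked = np.where(present, stored, np.uint64(np.iinfo(np.uint64).max))
    sw = np.lib.stride_tricks.sliding_window_view(masked, width)
    win_min = sw.min(axis=1)
    return win_present, win_min
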