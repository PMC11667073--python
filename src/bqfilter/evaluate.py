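"""Evaluation procedures: construction-FP measurement, s-sweeps, size bounds.

The quantities here mirror the structure's design trade-off: smaller
indexed s-mers shrink every slot by 2 bits per nucleotide removed, but
increase the chance that a random (absent) k-mer has all of its s-mers
present in the data — a *construction false positive*.  The probability
that a given s-mer appears by chance in a text with ``l`` distinct k-mers
is ``p_appear(s, l) = 1 - (1 - 4**-s)**l``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import hashing
from .index import BQFIndex, choose_q, _count_codes
from .rsqf import MAX_LOAD_FACTOR
from .synthetic import gen_reads

__all__ = [
    "p_appear",
    "bits_per_element_bounds",
    "truth_kmer_codes",
    "measure_fp_rate",
    "s_sweep",
    "FPReport",
    "EvalReport",
]


def p_appear(s: int, l: float) -> float:
    """Probability that a fixed s-mer occurs in a random text of length ``l``.

    ``1 - (1 - 4**-s)**l`` under a uniform ACGT model, computed stably for
    large ``l``.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if l < 0:
        raise ValueError("l must be >= 0")
    return float(-np.expm1(l * np.log1p(-(4.0 ** -s))))


def bits_per_element_bounds(n_elements: int, s: int, c: int) -> tuple[float, float]:
    """Space-per-element envelope (low_bound, high_bound) in bits.

    For ``n_elements`` distinct s-mers the smallest table with load
    <= 95 % is chosen; each slot then costs ``w = 2s - q + c + 3`` bits.
    ``low_bound = w / 0.95`` is the efficiency of a full table (95 % load,
    just before doubling); ``high_bound = w / 0.5`` of a half-full one
    (just after doubling).  The ratio low/high is exactly 0.5/0.95.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    q = choose_q(n_elements, s)
    w = 2 * s - q + c + 3
    return w / MAX_LOAD_FACTOR, w / 0.5


def truth_kmer_codes(reads: Iterable[str], k: int, canonical: bool = True) -> np.ndarray:
    """Sorted distinct (canonical) k-mer codes present in ``reads``."""
    codes, _counts = _count_codes(reads, k, canonical)
    return codes


@dataclass
class FPReport:
    """Outcome of a false-positive measurement."""

    n_queries: int
    n_false_positive: int
    n_true_present: int
    n_false_negative: int
    seed: int

    @property
    def fp_rate(self) -> float:
        return self.n_false_positive / self.n_queries

    @property
    def fp_rate_percent(self) -> float:
        return 100.0 * self.fp_rate


def measure_fp_rate(
    index: BQFIndex,
    n_queries: int,
    seed: int,
    truth: np.ndarray,
    read_len: int = 150,
    batch_reads: int = 20000,
) -> FPReport:
    """Query ``n_queries`` k-mers from fresh random sequences.

    ``truth`` is the sorted array of distinct (canonical) k-mer codes of the
    build reads (see :func:`truth_kmer_codes`).  A false positive is a
    queried k-mer reported present that is not in ``truth``; queried k-mers
    that are in ``truth`` are cross-checked and never counted as FP.
    """
    if n_queries < 1:
        raise ValueError("n_queries must be >= 1 (rate undefined otherwise)")
    truth = np.asarray(truth, dtype=np.uint64)
    k, s = index.k, index.s
    if read_len < k:
        read_len = 2 * k
    done = 0
    fp = 0
    tp = 0
    fn = 0
    batch_no = 0
    per_read = read_len - k + 1
    while done < n_queries:
        need_reads = -(-(n_queries - done) // per_read)
        reads = gen_reads(min(batch_reads, need_reads), read_len, seed * 1000003 + batch_no)
        batch_no += 1
        text = ("N".join(reads)).encode("ascii")
        present, valid_k, kcodes = _query_text(index, text)
        take = min(int(valid_k.sum()), n_queries - done)
        idx = np.flatnonzero(valid_k)[:take]
        pres = present[idx]
        in_truth = np.isin(kcodes[idx], truth, assume_unique=False)
        fp += int((pres & ~in_truth).sum())
        tp += int((pres & in_truth).sum())
        fn += int((~pres & in_truth).sum())
        done += take
    return FPReport(done, fp, tp, fn, seed)


def _query_text(index: BQFIndex, text: bytes):
    """k-mer presence over every window of ``text`` (N-separated reads).

    Returns ``(present, valid, kcodes)`` aligned on k-mer window starts;
    ``valid`` marks windows lying fully inside one read.
    """
    k, s = index.k, index.s
    z1 = k - s + 1
    scodes, svalid = hashing.encode_windows(text, s)
    if index.canonical:
        scodes = hashing.canonical_codes(scodes, s)
    hashes = hashing.hash_codes(scodes, s)
    spresent = np.zeros(scodes.size, dtype=bool)
    vidx = np.flatnonzero(svalid)
    pres_v, _cnt_v = index.filter.query_many(hashes[vidx])
    spresent[vidx] = pres_v
    # k-mer windows: all z1 s-mer windows valid and present
    cs_p = np.concatenate(([0], np.cumsum(spresent.astype(np.int64))))
    cs_v = np.concatenate(([0], np.cumsum(svalid.astype(np.int64))))
    nk = scodes.size - z1 + 1
    present = (cs_p[z1:] - cs_p[:-z1]) == z1
    valid = (cs_v[z1:] - cs_v[:-z1]) == z1
    kcodes, kvalid = hashing.encode_windows(text, k)
    if index.canonical:
        kcodes = hashing.canonical_codes(kcodes, k)
    assert kcodes.size == nk and np.array_equal(kvalid, valid)
    return present, valid, kcodes


@dataclass
class EvalReport:
    """Per-s rows of a sweep plus the experiment metadata."""

    rows: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows,
            columns=[
                "s",
                "n_distinct_smers",
                "fp_rate",
                "low_bound_bits_per_element",
                "high_bound_bits_per_element",
            ],
        )


def s_sweep(
    reads: Sequence[str],
    k: int,
    s_values: Iterable[int],
    c: int = 5,
    n_queries: int = 100000,
    seed: int = 0,
    canonical: bool = True,
) -> EvalReport:
    """Build one index per s and measure FP rate and size bounds.

    The distinct-s-mer count saturates at ``4**s`` for small s, and the FP
    rate collapses once ``p_appear(s, l)`` (l = number of distinct k-mers)
    becomes small.
    """
    reads = list(reads)
    truth = truth_kmer_codes(reads, k, canonical)
    report = EvalReport(
        meta={
            "seed": seed,
            "k": k,
            "c": c,
            "n_reads": len(reads),
            "n_queries": n_queries,
            "n_distinct_kmers": int(truth.size),
        }
    )
    for s in s_values:
        if not 1 <= s <= k:
            raise ValueError(f"s={s} outside [1, k]")
        codes, _ = _count_codes(reads, s, canonical)
        n_distinct = int(codes.size)
        index = BQFIndex.build_from_reads(reads, k=k, s=s, c=c, canonical=canonical)
        fpr = measure_fp_rate(index, n_queries, seed, truth)
        low, high = bits_per_element_bounds(n_distinct, s, c)
        report.rows.append((s, n_distinct, fpr.fp_rate, low, high))
    return report
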