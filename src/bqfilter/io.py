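"""File formats: counted dumps, FASTA/FASTQ reading, and index serialization.

The counted-dump dialect is the KMC text dump: one ``SEQUENCE<TAB>COUNT``
record per line, no header.  Sequence files may be FASTA or FASTQ,
optionally gzip-compressed; compression and format are auto-detected from
the file content, not the extension.

The binary index layout is little-endian and section-aligned:

====================  =======================================================
header                magic ``BQFX``, version byte, q/r/c/s/k (one byte
                      each), flags (bit0 canonical, bit1 log2 counters),
                      element count n (uint64), hash-constant fingerprint
                      (uint64)
occupieds             ``2**q`` bits packed into uint64 words
runends               ``2**q`` bits
offsets               ``2**q / 64`` uint64 words (64 bits per 64-slot block)
slots                 ``2**q`` records of ``r + c`` bits each, packed
                      big-endian-within-record, remainder then counter
====================  =======================================================

The payload sections together hold exactly ``size_bits()`` bits, which is
what makes the on-disk size match the structure's accounting formula
``2**q * (r + c + 3)``.
"""

from __future__ import annotations

import gzip
import struct
import warnings
from typing import IO, Iterator, Optional

import numpy as np
from Bio import SeqIO

from .hashing import HASH_FINGERPRINT
from .index import BQFIndex, CountedRecord
from .rsqf import RSQFilter

__all__ = [
    "read_counted_tsv",
    "write_counted_tsv",
    "read_sequences",
    "serialize",
    "deserialize",
]

_MAGIC = b"BQFX"
_VERSION = 1
_HEADER = struct.Struct("<4sB6BQQ")  # magic, version, q r c s k flags, n, fingerprint

_ACGT = frozenset("ACGT")


def _open_maybe_gzip(path, mode: str = "rt") -> IO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_counted_tsv(path) -> Iterator[CountedRecord]:
    """Stream ``SEQUENCE<TAB>COUNT`` records, validating as it goes."""
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected SEQUENCE<TAB>COUNT, got {line!r}"
                )
            seq, count_s = parts
            if not seq or not set(seq.upper()) <= _ACGT:
                raise ValueError(f"{path}: line {lineno}: invalid sequence {seq!r}")
            try:
                count = int(count_s)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: invalid count {count_s!r}"
                ) from None
            if count < 1:
                raise ValueError(f"{path}: line {lineno}: count must be >= 1")
            yield CountedRecord(seq.upper(), count)


def write_counted_tsv(records, path) -> int:
    """Write counted records; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.smer}\t{rec.count}\n")
            n += 1
    return n


def read_sequences(path) -> Iterator[tuple[str, str]]:
    """Yield ``(id, uppercased sequence)`` from FASTA or FASTQ (optionally gzipped)."""
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        fh.seek(0)
        if first == "":
            warnings.warn(f"{path}: empty sequence file", stacklevel=2)
            return
        if first == ">":
            fmt = "fasta"
        elif first == "@":
            fmt = "fastq"
        else:
            raise ValueError(f"{path}: neither FASTA nor FASTQ (starts with {first!r})")
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq).upper()


# ---------------------------------------------------------------------------
# Binary index format
# ---------------------------------------------------------------------------

_SLOT_CHUNK = 1 << 16  # slots per packing chunk; multiple of 8 keeps chunks byte-aligned


def _pack_slots(filt: RSQFilter) -> bytes:
    """Pack ``(remainder << c) | counter`` records into a contiguous bit stream."""
    w = filt.r + filt.c
    N = filt.num_slots
    out = bytearray()
    for lo in range(0, N, _SLOT_CHUNK):
        hi = min(lo + _SLOT_CHUNK, N)
        m = hi - lo
        bits = np.zeros((m, w), dtype=np.uint8)
        rem = filt.remainders[lo:hi]
        cnt = filt.counters[lo:hi]
        for j in range(filt.r):
            bits[:, j] = ((rem >> np.uint64(filt.r - 1 - j)) & np.uint64(1)).astype(np.uint8)
        for j in range(filt.c):
            bits[:, filt.r + j] = ((cnt >> np.uint64(filt.c - 1 - j)) & np.uint64(1)).astype(np.uint8)
        out += np.packbits(bits.reshape(-1)).tobytes()
    return bytes(out)


def _unpack_slots(data: bytes, filt: RSQFilter) -> None:
    w = filt.r + filt.c
    N = filt.num_slots
    expect = N * w // 8
    if len(data) != expect:
        raise ValueError(f"slot section has {len(data)} bytes, expected {expect}")
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))[: N * w].reshape(N, w)
    rem = np.zeros(N, dtype=np.uint64)
    cnt = np.zeros(N, dtype=np.uint64)
    for j in range(filt.r):
        rem |= bits[:, j].astype(np.uint64) << np.uint64(filt.r - 1 - j)
    for j in range(filt.c):
        cnt |= bits[:, filt.r + j].astype(np.uint64) << np.uint64(filt.c - 1 - j)
    filt.remainders = rem
    filt.counters = cnt


def serialize(index: BQFIndex, path) -> int:
    """Write the index; returns bytes written.

    The payload (everything after the header) is exactly
    ``index.filter.size_bits() / 8`` bytes.
    """
    f = index.filter
    flags = (1 if index.canonical else 0) | (2 if index.counter_mode == "log2" else 0)
    header = _HEADER.pack(
        _MAGIC, _VERSION, f.q, f.r, f.c, index.s, index.k, flags, f.n, HASH_FINGERPRINT
    )
    payload = (
        f.occupieds.words.astype("<u8").tobytes()
        + f.runends.words.astype("<u8").tobytes()
        + f.offsets.astype("<u8").tobytes()
        + _pack_slots(f)
    )
    assert len(payload) * 8 == f.size_bits()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(payload)
    return len(header) + len(payload)


def deserialize(path) -> BQFIndex:
    """Read an index written by :func:`serialize`; every query answer is preserved."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < _HEADER.size:
        raise ValueError(f"{path}: truncated header")
    magic, version, q, r, c, s, k, flags, n, fp = _HEADER.unpack_from(raw)
    if magic != _MAGIC:
        raise ValueError(f"{path}: not a BQF index (bad magic {magic!r})")
    if version != _VERSION:
        raise ValueError(f"{path}: unsupported format version {version}")
    if r != 2 * s - q:
        raise ValueError(f"{path}: inconsistent header (r={r} but 2s-q={2 * s - q})")
    if fp != HASH_FINGERPRINT:
        raise ValueError(f"{path}: index was built with different hash constants")
    filt = RSQFilter(q, r, c)
    N = filt.num_slots
    nw = N // 64
    sizes = [8 * nw, 8 * nw, 8 * nw, N * (r + c) // 8]
    off = _HEADER.size
    if len(raw) != off + sum(sizes):
        raise ValueError(f"{path}: truncated or oversized payload")
    sections = []
    for sz in sizes:
        sections.append(raw[off : off + sz])
        off += sz
    filt.occupieds.words = np.frombuffer(sections[0], dtype="<u8").astype(np.uint64)
    filt.runends.words = np.frombuffer(sections[1], dtype="<u8").astype(np.uint64)
    filt.offsets = np.frombuffer(sections[2], dtype="<u8").astype(np.int64)
    _unpack_slots(sections[3], filt)
    filt.n = n
    filt.rebuild_in_use()
    return BQFIndex(
        filt,
        k=k,
        s=s,
        canonical=bool(flags & 1),
        counter_mode="log2" if flags & 2 else "exact",
    )
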