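"""Rank/select bit vectors packed into 64-bit words.

``rank(v, i)`` counts the set bits in ``v[0..i]`` inclusive; ``select(v, j)``
returns the position of the j-th set bit (j counts from 1).  These two
operations, applied to the occupied/runend metadata vectors, are what lets a
quotient filter locate a possibly shifted run without sentinel values.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

__all__ = ["PackedBits", "rank_bits", "select_bits"]

_ONE = np.uint64(1)


class PackedBits:
    """Fixed-length bit vector on little-endian uint64 words.

    Bit ``i`` lives at bit ``i % 64`` of word ``i // 64``.  Length must be a
    multiple of 64 (the filter's slot count always is).
    """

    __slots__ = ("nbits", "words")

    def __init__(self, nbits: int, words: Optional[np.ndarray] = None):
        if nbits % 64:
            raise ValueError("PackedBits length must be a multiple of 64")
        self.nbits = nbits
        if words is None:
            self.words = np.zeros(nbits // 64, dtype=np.uint64)
        else:
            words = np.asarray(words, dtype=np.uint64)
            if words.size != nbits // 64:
                raise ValueError("word array does not match bit length")
            self.words = words.copy()

    @classmethod
    def from_bool_array(cls, bits: np.ndarray) -> "PackedBits":
        bits = np.asarray(bits, dtype=bool)
        packed = np.packbits(bits, bitorder="little")
        packed = np.pad(packed, (0, (-packed.size) % 8))
        out = cls(bits.size)
        out.words = packed.view(np.uint64).copy()
        return out

    def to_bool_array(self) -> np.ndarray:
        return np.unpackbits(self.words.view(np.uint8), bitorder="little")[: self.nbits].astype(bool)

    def get(self, i: int) -> int:
        return int((self.words[i >> 6] >> np.uint64(i & 63)) & _ONE)

    def set(self, i: int) -> None:
        self.words[i >> 6] |= _ONE << np.uint64(i & 63)

    def clear(self, i: int) -> None:
        self.words[i >> 6] &= ~(_ONE << np.uint64(i & 63))

    def assign(self, i: int, value: bool) -> None:
        if value:
            self.set(i)
        else:
            self.clear(i)

    def popcount(self) -> int:
        return sum(int(w).bit_count() for w in self.words)

    def rank(self, i: int) -> int:
        """Number of set bits in positions ``0..i`` inclusive."""
        if not 0 <= i < self.nbits:
            raise IndexError(f"rank index {i} out of range for {self.nbits} bits")
        j, t = i >> 6, i & 63
        total = 0
        for w in self.words[:j]:
            total += int(w).bit_count()
        total += (int(self.words[j]) & ((1 << (t + 1)) - 1)).bit_count()
        return total

    def select(self, j: int) -> Optional[int]:
        """Position of the j-th set bit (1-indexed count), or None."""
        if j < 1:
            raise ValueError("select count must be >= 1")
        seen = 0
        for wi, w in enumerate(self.words):
            w = int(w)
            pc = w.bit_count()
            if seen + pc >= j:
                need = j - seen
                while need > 1:
                    w &= w - 1
                    need -= 1
                return (wi << 6) + ((w & -w).bit_length() - 1)
            seen += pc
        return None

    def copy(self) -> "PackedBits":
        return PackedBits(self.nbits, self.words)


def _as_packed(vec) -> PackedBits:
    if isinstance(vec, PackedBits):
        return vec
    bits = np.asarray(list(vec) if not isinstance(vec, np.ndarray) else vec)
    if bits.dtype.kind in "US":  # allow "101101" style strings
        bits = np.array([int(ch) for ch in bits.tolist()] if bits.ndim else [int(ch) for ch in str(bits)], dtype=bool)
    bits = bits.astype(bool)
    padded = np.pad(bits, (0, (-bits.size) % 64))
    pb = PackedBits.from_bool_array(padded)
    pb_real_len = bits.size
    return _Truncated(pb, pb_real_len)


class _Truncated:
    """Length-checking view used by the module-level helpers."""

    def __init__(self, pb: PackedBits, nbits: int):
        self.pb = pb
        self.nbits = nbits

    def rank(self, i: int) -> int:
        if not 0 <= i < self.nbits:
            raise IndexError(f"rank index {i} out of range for {self.nbits} bits")
        return self.pb.rank(i)

    def select(self, j: int):
        pos = self.pb.select(j)
        return pos if pos is not None and pos < self.nbits else None


def rank_bits(vec: "Iterable[int] | str | PackedBits", i: int) -> int:
    """Set bits in ``vec[0..i]`` inclusive; ``vec`` may be bits, a 0/1 string, or PackedBits."""
    if isinstance(vec, str):
        vec = [int(ch) for ch in vec]
    return _as_packed(vec).rank(i)


def select_bits(vec: "Iterable[int] | str | PackedBits", j: int) -> Optional[int]:
    """Position of the j-th set bit (1-indexed), or None if fewer than j bits are set."""
    if isinstance(vec, str):
        vec = [int(ch) for ch in vec]
    return _as_packed(vec).select(j)
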