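"""2-bit DNA codes and the invertible 2s-bit hash.

Every word over {A, C, G, T} of length ``s`` is identified with an integer in
``[0, 4**s)`` under the fixed mapping A=0, C=1, G=2, T=3, most significant
digit first.  This makes the encoding strictly monotone in lexicographic
order and makes complementation ``digit -> 3 - digit``.

The hash is a bijection on ``[0, 2**(2s))`` built from invertible steps only
(xor-with-right-shift and multiplication by an odd constant, everything
modulo ``2**(2s)``).  Because it is a bijection, membership answers of the
filter are exact at the s-mer level and stored elements can be decoded back
to their s-mer string, which is what makes enumeration and resizing
possible.  The same constants are used for every ``s``; they are frozen here
and fingerprinted in the serialized index header so that index files are
portable across versions.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "encode_smer",
    "decode_smer",
    "revcomp",
    "canonical",
    "hash_2s",
    "unhash_2s",
    "encode_windows",
    "revcomp_codes",
    "canonical_codes",
    "hash_codes",
    "split_hash",
    "join_hash",
    "HASH_FINGERPRINT",
    "MAX_S",
]

# 2s <= 62 keeps every value inside one 64-bit word.
MAX_S = 31

_BASE_OF = {"A": 0, "C": 1, "G": 2, "T": 3, "a": 0, "c": 1, "g": 2, "t": 3}
_CHAR_OF = "ACGT"

# Odd multipliers (murmur3 fmix64) and shift amounts; any shift >= 2s makes
# that xorshift step a no-op, which is still a bijection.
_MULT1 = 0xFF51AFD7ED558CCD
_MULT2 = 0xC4CEB9FE1A85EC53
_SHIFTS = (33, 29, 32)

#: Stable identifier of the hash-constant set, stored in index headers.
HASH_FINGERPRINT = (_MULT1 ^ _MULT2 ^ (_SHIFTS[0] << 1) ^ (_SHIFTS[1] << 17) ^ (_SHIFTS[2] << 33)) & 0xFFFFFFFFFFFFFFFF

# ASCII lookup table: A/C/G/T (either case) -> 0..3, everything else -> 255.
_ASCII_CODE = np.full(256, 255, dtype=np.uint8)
for _ch, _v in _BASE_OF.items():
    _ASCII_CODE[ord(_ch)] = _v


def encode_smer(seq: str) -> int:
    """Encode an ACGT string as its base-4 integer (A=0, C=1, G=2, T=3, MSB first).

    Lowercase letters are accepted (FASTA soft-masking).  A non-ACGT
    character raises ``ValueError`` naming the offending position.
    """
    if len(seq) > MAX_S:
        raise ValueError(f"word of length {len(seq)} exceeds the {MAX_S} nt limit")
    code = 0
    for pos, ch in enumerate(seq):
        try:
            code = (code << 2) | _BASE_OF[ch]
        except KeyError:
            raise ValueError(f"non-ACGT character {ch!r} at position {pos}") from None
    return code


def decode_smer(code: int, s: int) -> str:
    """Exact inverse of :func:`encode_smer` for words of length ``s``."""
    if not 0 <= code < (1 << (2 * s)):
        raise ValueError(f"code {code} out of range for s={s}")
    out = []
    for shift in range(2 * (s - 1), -1, -2):
        out.append(_CHAR_OF[(code >> shift) & 3])
    return "".join(out)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "a": "T", "c": "G", "g": "C", "t": "A"}
    try:
        return "".join(comp[ch] for ch in reversed(seq))
    except KeyError:
        raise ValueError(f"non-ACGT character in {seq!r}") from None


def canonical(seq: str) -> str:
    """The smaller of ``seq`` and its reverse complement under encode order.

    Encode order coincides with lexicographic order under A<C<G<T, so this
    is the usual canonical k-mer.  The result is uppercase.
    """
    fwd = seq.upper()
    rc = revcomp(fwd)
    return fwd if fwd <= rc else rc


def _mask(s: int) -> int:
    return (1 << (2 * s)) - 1


def hash_2s(x: int, s: int) -> int:
    """Invertible hash of a 2s-bit integer onto ``[0, 2**(2s))``."""
    m = _mask(s)
    if not 0 <= x <= m:
        raise ValueError(f"value {x} out of range for s={s}")
    x ^= x >> _SHIFTS[0]
    x = (x * _MULT1) & m
    x ^= x >> _SHIFTS[1]
    x = (x * _MULT2) & m
    x ^= x >> _SHIFTS[2]
    return x


@lru_cache(maxsize=None)
def _inv_mult(mult: int, w: int) -> int:
    return pow(mult & ((1 << w) - 1), -1, 1 << w)


def _inv_xorshift(y: int, shift: int, w: int) -> int:
    # x ^= x >> shift unfolds in ceil(w/shift) steps.
    x = y
    for _ in range(-(-w // shift)):
        x = y ^ (x >> shift)
    return x


def unhash_2s(y: int, s: int) -> int:
    """Exact inverse of :func:`hash_2s` (steps inverted in reverse order)."""
    w = 2 * s
    m = _mask(s)
    if not 0 <= y <= m:
        raise ValueError(f"value {y} out of range for s={s}")
    x = _inv_xorshift(y, _SHIFTS[2], w)
    x = (x * _inv_mult(_MULT2, w)) & m
    x = _inv_xorshift(x, _SHIFTS[1], w)
    x = (x * _inv_mult(_MULT1, w)) & m
    x = _inv_xorshift(x, _SHIFTS[0], w)
    return x


def split_hash(h: int, q: int, r: int) -> tuple[int, int]:
    """Split a (q+r)-bit hash into (quotient = top q bits, remainder = low r bits)."""
    return h >> r, h & ((1 << r) - 1)


def join_hash(quotient: int, remainder: int, r: int) -> int:
    return (quotient << r) | remainder


# ---------------------------------------------------------------------------
# Vectorized versions over numpy uint64 arrays (the bulk build / query path).
# ---------------------------------------------------------------------------

def encode_windows(seq: bytes | str, s: int) -> tuple[np.ndarray, np.ndarray]:
    """All length-``s`` window codes of ``seq`` plus a validity mask.

    Returns ``(codes, valid)`` where ``codes`` has one entry per window
    start (``len(seq) - s + 1`` of them, empty if the sequence is shorter
    than ``s``) and ``valid`` is False for windows containing a non-ACGT
    character.  Invalid windows carry an arbitrary code and must be ignored
    by the caller.
    """
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(seq, dtype=np.uint8)
    n = arr.size - s + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    base = _ASCII_CODE[arr]
    bad = base == 255
    # window is valid iff it contains no bad base
    cs = np.concatenate(([0], np.cumsum(bad, dtype=np.int64)))
    valid = (cs[s:] - cs[:-s]) == 0
    b = np.where(bad, 0, base).astype(np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(s):
        codes |= b[j : j + n] << np.uint64(2 * (s - 1 - j))
    return codes, valid


def revcomp_codes(codes: np.ndarray, s: int) -> np.ndarray:
    """Vectorized reverse complement on encoded words."""
    out = np.zeros_like(codes, dtype=np.uint64)
    c = codes.astype(np.uint64, copy=False)
    three = np.uint64(3)
    for j in range(s):
        digit = (c >> np.uint64(2 * (s - 1 - j))) & three
        out |= (three - digit) << np.uint64(2 * j)
    return out


def canonical_codes(codes: np.ndarray, s: int) -> np.ndarray:
    return np.minimum(codes, revcomp_codes(codes, s))


def hash_codes(codes: np.ndarray, s: int) -> np.ndarray:
    """Vectorized :func:`hash_2s` (identical output, element-wise)."""
    m = np.uint64(_mask(s))
    x = codes.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(_SHIFTS[0])
        x *= np.uint64(_MULT1)
        x &= m
        x ^= x >> np.uint64(_SHIFTS[1])
        x *= np.uint64(_MULT2)
        x &= m
        x ^= x >> np.uint64(_SHIFTS[2])
    return x
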