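"""Seeded synthetic read generation.

Uniform i.i.d. ACGT reads are the negative-query model behind the
construction-false-positive analysis: the chance that a word of length s
appears in a random text of length l is ``1 - (1 - 4**-s)**l``, which is
what makes short s-mers explode the construction FP rate.  A GC-bias knob
is exposed for exploration but the defaults are uniform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gen_reads", "gen_read_iter"]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def gen_reads(n_reads: int, read_len: int, seed: int, gc: float = 0.5) -> list[str]:
    """``n_reads`` i.i.d. reads of ``read_len`` nt; identical for identical seeds."""
    if n_reads < 0 or read_len < 1:
        raise ValueError("need n_reads >= 0 and read_len >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draws = rng.choice(4, size=(n_reads, read_len), p=p) if gc != 0.5 else rng.integers(
        0, 4, size=(n_reads, read_len)
    )
    chars = _ALPHABET[draws]
    return [row.tobytes().decode("ascii") for row in chars]


def gen_read_iter(n_reads: int, read_len: int, seed: int, batch: int = 10000, gc: float = 0.5):
    """Stream reads in seeded batches (memory-friendly for large read sets)."""
    made = 0
    sub = 0
    while made < n_reads:
        m = min(batch, n_reads - made)
        yield from gen_reads(m, read_len, seed * 100003 + sub, gc=gc)
        made += m
        sub += 1
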