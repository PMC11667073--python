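"""Independent oracles used by the test suite.

Everything here is deliberately naive (linear scans, dictionaries, direct
formula evaluation) and shares no code with the structures under test
beyond the public hash helpers.
"""

from __future__ import annotations

import numpy as np


def naive_rank(bits, i: int) -> int:
    """Set bits in bits[0..i] inclusive, by direct scan."""
    return int(sum(1 for b in bits[: i + 1] if b))


def naive_select(bits, j: int):
    """Position of the j-th set bit (1-indexed), by direct scan."""
    seen = 0
    for pos, b in enumerate(bits):
        if b:
            seen += 1
            if seen == j:
                return pos
    return None


def global_runend_position(filt, i: int):
    """The un-blocked rank/select formula, evaluated in an unrolled frame.

    Rotates the metadata vectors so that they start just after an empty
    slot (the table is circular), then applies
    ``select(runends, rank(occupieds, i))`` literally.  Independent of the
    filter's block offsets.
    """
    occ = filt.occupieds.to_bool_array()
    rend = filt.runends.to_bool_array()
    use = filt.in_use.to_bool_array()
    if not occ[i]:
        return None
    N = occ.size
    empty = np.flatnonzero(~use)
    assert empty.size, "oracle needs an empty slot"
    shift = (int(empty[0]) + 1) % N
    occ_u = np.roll(occ, -shift)
    rend_u = np.roll(rend, -shift)
    i_u = (i - shift) % N
    d = naive_rank(occ_u, i_u)
    pos_u = naive_select(rend_u, d)
    assert pos_u is not None
    return (pos_u + shift) % N


def run_layout(filt):
    """Decode (quotient -> list of (remainder, counter)) by brute scan."""
    out = {}
    N = filt.num_slots
    for x in range(N):
        e = filt.runend_position(x)
        if e is None:
            continue
        # walk back to the run start
        items = []
        p = e
        while True:
            items.append((int(filt.remainders[p]), int(filt.counters[p])))
            if p == x:
                break
            p1 = (p - 1) % N
            if filt.runends.get(p1) or not filt.in_use.get(p1):
                break
            p = p1
        out[x] = list(reversed(items))
    return out


def runs_strictly_ascending(filt) -> bool:
    for _x, items in run_layout(filt).items():
        rems = [rm for rm, _ in items]
        if rems != sorted(set(rems)):
            return False
    return True


def smer_counts_dict(reads, s: int, canonical: bool):
    """Naive s-mer counter over a read set (dictionary oracle)."""
    from bqfilter.hashing import canonical as canon

    counts: dict[str, int] = {}
    for read in reads:
        read = read.upper()
        for i in range(len(read) - s + 1):
            w = read[i : i + s]
            if set(w) - set("ACGT"):
                continue
            if canonical:
                w = canon(w)
            counts[w] = counts.get(w, 0) + 1
    return counts
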