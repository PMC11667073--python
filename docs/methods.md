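# Methods

## Model

The package implements a counting filter for DNA words built from three
layers.

**Encoding and hashing.**  A word over {A,C,G,T} of length `s` is its
base-4 integer (A=0, C=1, G=2, T=3, most-significant digit first), so the
encoding is monotone in lexicographic order and complementation is
`digit → 3 − digit`.  The hash is a bijection on `[0, 2^2s)` composed of
invertible steps only: `x ^= x >> 33`, `x *= 0xff51afd7ed558ccd`,
`x ^= x >> 29`, `x *= 0xc4ceb9fe1a85ec53`, `x ^= x >> 32`, everything
modulo `2^2s` (the murmur3 finalizer constants; a shift ≥ 2s degenerates
to the identity, which is still invertible).  The same constants serve
every `s` and are fingerprinted into the serialized header.  Inverses use
the modular inverse of each odd multiplier and iterated unfolding of the
xorshifts.  Exhaustive permutation checks at small `s` and randomized
round-trips at `s = 19, 31` are part of the test suite.  Bijectivity is
what gives exact s-mer membership, enumeration, and resizability; nothing
in the design depends on the specific constants.

**Rank-and-select quotient filter.**  The table has `2^q` slots; a hash
splits into quotient = top `q` bits and remainder = low `r = 2s − q`
bits.  Quotient-sharing elements form runs in ascending remainder order;
`occupied` and `runend` bit vectors plus the formula
`runend_position(i) = select(runends, rank(occupieds, i))` locate runs,
with one 64-bit offset checkpoint per 64-slot block so that rank/select
never scan more than a cluster.  The quotient is taken from the *top* of
the hash so that doubling the table (at > 95 % load) promotes the
remainder's most significant bit into the address: each run splits into
two adjacent runs and the whole resize is a linear re-placement of the
hash-sorted elements.  Each slot also carries a `c`-bit counter that
saturates at `2^c − 1`; duplicate insertions merge by saturating
addition.  Size is exactly `2^q (r + c + 3)` bits — the 3 metadata bits
are occupied + runend + the amortized offset (full 64-bit offsets, one
per block, are deliberately used instead of a denser 2.125-bit amortized
encoding; alignment beats the ~0.9 bit/slot saving).

**s-mer emulation.**  The index stores the s-mers of the dataset and
answers a k-mer query as the minimum stored counter over its `k − s + 1`
s-mers, absent if any s-mer is absent.  This trades `2(k − s)` bits per
slot for construction false positives, whose driver is
`p_appear(s, l) = 1 − (1 − 4^(−s))^l` with `l` approximated by the
number of distinct k-mers.

## Conventions and parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `k` | query word length (nt) | 31 | ≤ 31 (2k ≤ 62 bits) |
| `s` | indexed word length (nt) | 19 | `s ≤ k`; FP rate explodes for small `s` |
| `c` | counter bits | 5 | cap `2^c − 1 = 31`; answers at the cap are flagged as lower bounds |
| `q` | address bits | fitted | smallest `q` with `n/2^q ≤ 0.95`; `6 ≤ q ≤ 2s` |
| `min_count` | abundance filter at build | 1 | set 2 to mimic "seen at least twice" preprocessing |
| canonical | merge reverse complements | on | matches KMC-style counted input |
| counter mode | `exact` or `log2` | exact | `log2` stores `floor(log2 count)`; index becomes read-only |

Saturation is reported as "≥ 2^c − 1": the stored cap is `2^c − 1`, so
that is the bound that is provably correct.

Degenerate/edge behaviour: `r = 0` is a legal terminal geometry (the
address consumes the whole hash; runs are singletons; resize is refused);
a zero remainder is a legal stored value — emptiness is tracked purely by
metadata; runs wrap circularly past the last slot; counter value 0 is
never stored (presence implies abundance ≥ 1); windows containing
non-ACGT characters are skipped at build time and reported absent at
query time.

## Implementation notes

In memory the slot payload lives in two value arrays (remainders,
counters) beside the packed metadata bit vectors; the packed
`(r + c)`-bit slot layout exists on disk, where the payload sections hold
exactly `size_bits()` bits.  A derived in-use bitvector accelerates
empty-slot scans; it is reconstructed from occupieds/runends/offsets on
deserialization and is excluded from the size accounting.

Single-element insert and delete decode the contiguous in-use region
around the affected cluster and greedily re-place its runs
(`start = max(quotient, previous_end + 1)` in a frame unrolled at the
preceding empty slot) — O(cluster) per operation and immune to
wrap-around corner cases.  Bulk construction and resize vectorize the
same greedy recurrence over all hash-sorted elements (a
`maximum.accumulate` with a one- or two-pass fixpoint for the wrapped
tail) and then derive all block offsets at once from
`max(0, select(runends, rank(occupieds, B)) − B)` evaluated in the
unrolled frame.  Tests assert that both paths produce bit-identical
layouts and that block-accelerated `runend_position` equals the global
formula on randomized filters.

The resize trigger is checked before each insert and fires when
`(n + 1)/2^q > 0.95`.  Offsets are signed 64-bit internally and written
as unsigned little-endian words.

## Synthetic data and what the tests show

`gen_reads` draws i.i.d. uniform ACGT reads (seeded; an optional GC-bias
knob exists but defaults to uniform).  This matches the negative-query
model and the assumption behind `p_appear`; it does **not** reproduce the
repeat structure, coverage correlation, or base-composition skew of real
sequencing data.  Consequences: the distinct-s-mer count grows almost
linearly with text size (real metagenomes grow sub-linearly for
`s > 17`), and the s value at which construction false positives explode
sits wherever `p_appear(s, l)` turns on for the synthetic `l` — smaller
than the ~17 nt threshold quoted for multi-hundred-million-element
metagenomes.  Passing tests therefore validate the structure and the FP
*mechanism*, not a specific real-data threshold.

The headline experiment (`scripts/acceptance.py`, also an end-to-end
test) uses 50 000 reads × 150 nt (6.6 M distinct canonical 19-mers,
`q = 23`, load 0.79) and ten million random 31-mer queries.  These sizes
were chosen as the largest desk-scale configuration in which the
expected construction-FP count is still essentially zero and the whole
run takes minutes on one CPU; the measured FP rate, bits/element and
bound curves are computed fresh on every run.

## Design choices made where the design was open

- **Canonicalization** is a flag, default on, because counted k-mer
  dumps are conventionally canonical; all queries canonicalize their
  s-mers when the flag is set.
- **Quotient from the top bits** (see resize rationale above); the
  alternative (low bits) would make resize a full reshuffle.
- **Offset convention** for block-leading slots not inside any run is
  "0", and otherwise the distance to the runend of the last run whose
  quotient is at or before the slot — the operational rank-and-select
  convention, validated against the global formula.
- **Deletion** is supported only with exact counters; in `log2` mode
  incremental updates are rejected because bucketed counts cannot be
  decremented meaningfully.
- **`l` in `p_appear`** is taken as the number of distinct k-mers of the
  text.
- Truth sets in the evaluation layer are plain arrays/dictionaries —
  exact and comfortably sized at desk scale (≤ 10^7 distinct words).

## Known limitations

One sample per index (no colored queries).  k-mers cannot be enumerated,
only s-mers.  Words above 31 nt are unsupported.  The fimpera minimum can
overestimate a k-mer's true abundance (bounded by its rarest s-mer's
count); this overestimation is inherited from the emulation scheme and is
not re-quantified here.  Throughput is that of a pure-Python/numpy
implementation: suitable for desk-scale datasets (millions of elements),
not for the billion-element regime the design targets in compiled form.
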