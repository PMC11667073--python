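# bqfilter — a backpack quotient filter for k-mer abundance indexing

`bqfilter` indexes the k-mer content of a sequencing dataset *with
abundances* in a dynamic, space-efficient structure: a rank-and-select
quotient filter whose slots carry a small saturating counter (the
"backpack"), combined with s-mer emulation of k-mer queries.  It is aimed
at metagenomic-scale membership/abundance queries — pseudo-alignment
against one sample, abundance screening, k-mer set comparisons — where a
hash table is too large and static structures cannot grow.

## The structure in one paragraph

Every s-mer (a DNA word of length `s ≤ k`) is encoded on `2s` bits and
passed through an invertible xorshift-style hash.  The hash value splits
into a **quotient** `h0` (the top `q` bits, used as a table address) and a
**remainder** `h1` (the low `r = 2s − q` bits, stored in the slot).  Slots
also hold a `c`-bit saturating counter for the s-mer's abundance.
Elements sharing a quotient form a *run* stored in ascending remainder
order; two metadata bits per slot (`occupied`, `runend`) plus one 64-bit
offset checkpoint per 64-slot block let rank/select locate any run in
near-constant time.  Total size is exactly

```
2^q × (r + c + 3) bits        r = 2s − q
```

Because the hash is a bijection, s-mer lookups are exact, stored elements
can be enumerated (and decoded back to their sequence), and the table can
be doubled — `q+1` address bits, `r−1` remainder bits — whenever the load
factor `n / 2^q` would pass 95 %, so there is no capacity limit.

A k-mer query is answered fimpera-style as the **minimum counter over its
`k − s + 1` constituent s-mers**, and "absent" as soon as any s-mer is
absent.  Storing s-mers instead of k-mers saves `2(k − s)` bits per slot;
the price is a *construction false positive* rate — a k-mer absent from
the data can have all its s-mers present — governed by the probability
`1 − (1 − 4^(−s))^l` that a random s-mer appears in a text with `l`
distinct k-mers.  For realistic `l` this rate collapses once `s` exceeds
~17 and stays below 10⁻⁵ %.

## Worked example

Index 2 000 synthetic 150 nt reads and query them back:

```sh
$ bqf build --reads example.fa --k 31 --s 19 --c 5 -o example.bqf
indexed 264000 s-mers (s=19, k=31, q=19); wrote 1769499 bytes to example.bqf

$ bqf stats --index example.bqf
k       31
s       19
q       19
r       19
c       5
n       264000
canonical       True
counter_mode    exact
load_factor     0.5035400390625
size_bits       14155776
size_bytes      1769472
bits_per_element        53.620363636363635
```

The 264 000 distinct canonical 19-mers landed in a `2^19`-slot table at
50 % load; each slot costs `r + c + 3 = 27` bits, hence
`2^19 × 27 = 14 155 776` bits, i.e. 53.6 bits per element at this load
(the on-disk payload is exactly `size_bits / 8` bytes plus a 27-byte
header).  At this small scale the table is half empty — space efficiency
improves as the table fills toward 95 %, and at metagenomic scale
(billions of elements, larger `q`, hence smaller `r`) it reaches the
13–26 bits/element regime the structure is designed for.

```sh
$ bqf query --index example.bqf --reads example.fa -o hits.tsv
```

`hits.tsv` has one row per k-mer window: `sequence_id`, 0-based window
`position`, `abundance`, a `saturated` flag (1 means the counter hit
`2^c − 1 = 31` and the value is a lower bound), and `present`.  Querying
the build reads themselves reports every window present (the structure
has no false negatives); a read from the first batch gives 120 windows,
all present, with minimum abundance 1.

`bqf eval fp` and `bqf eval s-sweep` run the synthetic evaluation
experiments (construction FP rate; FP/size trade-off across `s`).

## Library use

```python
from bqfilter import BQFIndex, gen_reads

reads = gen_reads(2000, 150, seed=7)
index = BQFIndex.build_from_reads(reads, k=31, s=19, c=5)
hit = index.query_kmer(reads[0][:31])   # Abundance(value=1, saturated=False)
```

`BQFIndex.build_from_counts` consumes KMC-style `SEQUENCE<TAB>COUNT`
dumps; `serialize`/`deserialize` round-trip the index through the
documented binary format; `RSQFilter` exposes the underlying filter
(insert / query / delete / enumerate / resize).

## Limitations

Single-sample indexing only (no colored queries); k-mers cannot be
enumerated, only the stored s-mers; in `log2` counter mode the index is
read-only after construction; words longer than 31 nt are not supported
(hashes must fit in 64 bits).
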