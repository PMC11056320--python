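# capssa

Parallel-by-design, cache-friendly construction of the **suffix array**
(SA) and **longest-common-prefix array** (LCP) of a byte text, built on
a samplesort partitioning scheme whose every suffix comparison happens
inside an **LCP-informed merge**.

## Who this is for

Genome indexing pipelines (read aligners, enhanced-suffix-array lookup,
de Bruijn contig indexing) need the SA of texts with billions of
symbols, and usually want the LCP array too.  `capssa` implements the
samplesort + LCP-mergesort construction as a tested Python library with
compiled (numba) kernels, a thin `capssa` command-line tool, and full
instrumentation of the algorithm's comparison accounting, partition
balance and working space — making it equally useful as a reference
implementation for studying the algorithm as for indexing moderate-size
texts.

## The algorithm

For a text `T` of length `n` ending in a unique smallest terminator
`$`, the suffix array `SA` lists the start positions of all suffixes in
lexicographic order, and `L[i] = LCP(T[SA[i]:], T[SA[i-1]:])` (with
`L[0] = 0`).  Construction proceeds in four steps:

1. **Local sorting.** The identity permutation of `[0, n)` is split
   into `p` uniform subarrays; each is sorted by a mergesort whose
   merge propagates run-local LCP values.  When merging runs `X` and
   `Y`, with `m` the LCP of the last compared pair and `l_x` the LCP of
   the freshly advanced element to its run predecessor, the cases
   `l_x > m` and `l_x < m` are decided in O(1) with **no symbol
   comparison**; only `l_x = m` compares symbols, starting at offset
   `m`.
2. **Pivot selection.** `s` suffixes are sampled from each sorted run;
   the `s·p` samples are sorted and the `p−1` evenly spaced order
   statistics become global pivots.  With `s = 32 ln n` every partition
   has size at most `c·n/p` with high probability.
3. **Collation.** Each pivot's upper-bound position in each run is
   found by binary search with the *simple accelerant* (comparisons
   resume at the minimum of the pivot's LCP against the lo/hi bounds);
   the cuts split every run into sub-subarrays, which are regrouped so
   each partition's pieces are contiguous.
4. **Partition merging.** Each partition's `p` sorted groups are merged
   pairwise with the same LCP-informed merge; boundary LCP values
   between partitions are computed at the end.

Total symbol comparisons are `O(n log n + Σ L_i)`; the *matching*
comparisons accumulate exactly into the final LCP values (with one
partition, `matching = Σ L_i` as an identity, which the test suite
asserts).  Working space is 4n entries (two ping-pong buffer pairs).

A **bounded-context** mode (order `k`) declares suffixes equal once
they share `k` symbols, supporting queries of length ≤ `k` at a cost of
at most `O(n log n + nk)` comparisons — a large saving on repetitive
texts.

## Worked example

```python
import capssa as cs

text = cs.build_text("AACTGCGGAT", terminator="$")
sa, lcp, stats = cs.construct(text, cs.BuildConfig(p=2, s=2))
print(sa.tolist())   # [10, 0, 1, 8, 5, 2, 7, 4, 6, 9, 3]
print(lcp.tolist())  # [0, 0, 1, 1, 0, 1, 0, 1, 1, 0, 1]
```

Row 3, for instance, says the third-smallest suffix is `AT$` (start 8)
and it shares 1 leading symbol (`A`) with its predecessor `ACTGCGGAT$`.
`examples/worked_example.py` prints the full table;
`examples/bounded_context.py` and `examples/partition_balance.py`
demonstrate the context bound and pivot oversampling.  From a shell:

```
capssa gen --kind random -n 100000 -o genome.fa
capssa build genome.fa -o genome_idx -p 8 --verify
capssa stats genome_idx
```

`build` writes `genome_idx.sa` / `genome_idx.lcp` (raw little-endian
unsigned integers, width 4 or 8 bytes) plus a JSON sidecar with the
configuration, text checksum and instrumentation counters.

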