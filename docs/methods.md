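# Methods

## Model and conventions

The indexed object is a byte string with an appended terminator that is
unique and strictly smaller than every other byte present (0x00 by
default; rendered `$` in text form).  All suffixes are therefore
distinct and the suffix array is a true permutation of `[0, n)` with a
total order.  Positions are 0-based, intervals half-open, and the first
LCP entry is fixed at 0 (the first suffix has no predecessor; this also
matches the standard printed form of the array).  Inputs that already
contain the terminator byte are rejected rather than remapped, so the
text round-trips exactly.

## The merge kernel

The merge of two sorted runs carries one piece of state, `m`, the LCP
of the last compared pair, and reads each freshly advanced element's
run-local LCP `l`.  `l > m` and `l < m` emit without touching the text;
`l = m` compares symbols starting at offset `m` (the shared prefix is
implied by transitivity through the last emitted element, so the skip
needs no re-verification).  The first comparison of a merge starts from
`m = 0`, which coincides with the run invariant `lcps[0] = 0`, so no
special case is needed.  The side roles are symmetric and both are
implemented explicitly.  On depletion the remaining entries are copied
and the first copied entry receives the current `m` — by the invariant
`m` is exactly its LCP to the last emitted element.

Matching and mismatching symbol comparisons are counted separately.
Matched symbols accumulate into output LCP values, so after a
single-partition build `matching == Σ L_i` is an exact identity (the
suite asserts it, including the closed form m(m−1)/2 for a unary text);
mismatches are at most one per merge step, hence ≤ n·ceil(log₂ n) for a
full sort.

Mergesort is realised bottom-up (widths 1, 2, 4, …) over two ping-pong
buffer pairs rather than by literal recursion: the merge tree and hence
the comparison accounting are identical, there is no insertion-sort
cutoff (which could perturb the accounting), and the iterative form
compiles cleanly.  Partition merging reduces the group list by pairwise
passes over the same kind of buffer pair, bottoming out at sorted
groups instead of singletons; empty groups (a pivot need not split
every run) simply vanish from the boundary list.

## Pivots, placement, collation

Sampling is uniform **without replacement** per run, one child stream
per run split off the build seed (`numpy.random.SeedSequence.spawn`),
so results are reproducible and independent of scheduling.  The global
pivots are the sorted samples at 0-based ranks `s, 2s, …, (p−1)s`.  A
sampling factor exceeding the shortest run is clamped with a logged
warning.  Default `s = 64` is a practical balance-vs-overhead choice;
the balance property is tested at the theoretically motivated
`s = ceil(32 ln n)`.

Pivot placement is an upper-bound binary search — the last index where
the pivot could be inserted without breaking the order — using plain
accelerated comparisons (the pivot's LCP against the lo and hi bounds
is tracked and each probe starts at their minimum), not LCP-array-
guided search.  With a finite `prefix_limit` only that many symbols of
the pivot are considered and a probe that exhausts the limit ranks
*greater* ("extends beyond an equal prefix").  The pivot's own suffix
is treated by the same rule in truncated mode: any exception for the
identity pair would make the cut predicate non-monotone inside a run
containing other suffixes with the same limited prefix, and an
upper-bound search over a non-monotone predicate is ill-defined.  Ties
produced by the context bound alone (and the identity pair in
non-truncated mode) rank *not greater*.  Either way the cut predicate
is monotone in suffix order, so every partition is a contiguous range
of the final order and the final array is correct for **any**
`prefix_limit ≥ 1` — the trade-off is only in partition balance.

Collation copies each run's j-th sub-subarray into partition j in run
order, resetting the first LCP of every copied block to 0 (its
predecessor changed); boundary LCP values between partitions are
recomputed at the very end by direct suffix comparison.

## Bounded context

With context bound `k`, every comparison stops at an LCP of `k` and
reports a tie; merge ties take the x-side element first (stable-left),
which makes the output deterministic and independent of worker count.
Reported LCP values are capped at `k`, keeping the array meaningful for
queries of length ≤ `k`.  Because a true LCP in a terminated text never
reaches `n`, a bound `k ≥ n` follows exactly the full-context code path
and the outputs are bit-identical.  The bounded output is validated as
*a* valid k-order (permutation, pairwise k-bounded order, capped LCP
values) rather than against a canonical tie-break; the brute-force
oracle's own convention for ties is ascending start position.

## Parallelism and working space

Parallelism is a contract, not a primitive: subarray sorts and
partition merges are independent tasks, the serial schedule implemented
here is the reference, and any parallel schedule must produce
bit-identical output (the seeded sampling and stable-left ties make
this achievable).  The `workers` field only feeds the default partition
count `p = min(workers, max(1, n // 4096))`.

The linear-space contract is 4n entries: at any level of the sorts the
merge instances hold 2n input plus 2n output entries (two ping-pong
pairs).  The instrumentation tracks the peak number of concurrently
live working entries across the serial schedule — per-chunk sort
buffers plus retained runs, the collated arrays, and the single
partition-size scratch pair — and the suite asserts peak ≤ 4n on every
input class.  The O(s·p) pivot-sampling workspace is lower-order and
reported separately (`sampling_entries`); on degenerate inputs where
p ≈ n it can rival n, which is a property of sampling itself, not of
the merge machinery the 4n budget describes.

## Synthetic data

The generators cover the regimes that drive suffix-sorting cost:
i.i.d. uniform DNA (mean LCP ~ log₄ n — the benign, genome-like case),
periodic and unary texts (mean LCP of order n — the extremely
repetitive, pathological case), and Fibonacci words (a standard
highly-repetitive stress family with non-trivial structure).  They are
deterministic for a fixed seed.  What they do not emulate: real-genome
composition (GC bias, repeat families, N-runs, soft-masking) or
chromosome structure, so passing tests demonstrate algorithmic
correctness and the claimed accounting/balance/space behaviour, not
wall-clock performance on real assemblies.

## Problem sizes and numerical choices

The suite exercises oracle equivalence on 200 random texts up to
n = 2000 (alphabet sizes 2–20) plus adversarial texts, across
p ∈ {1, 2, 3, 8} and prefix limits {1, 16, ∞}; partition balance on
random DNA at n = 10⁵, p = 16 over 20 seeds; and the bounded-context
sweep on a periodic text at n = 10⁵ with k ∈ {1024, 256, 64}.  These
sizes make every claim measurable in seconds while leaving the scaling
behaviour visible.  Entry width for on-disk arrays is 4 bytes when all
values fit below 2³², else 8 ("auto"), and an overflow at width 4 is a
hard error that names the remedy.  Degenerate inputs: the empty body is
legal (the text is then just the terminator), `p > n` is clamped with a
warning, and empty merge inputs/groups are identities.

## Known limitations

Worst-case work is output-sensitive (quadratic on adversarial texts at
full context); the binary searches can cost O(n log(n/p)) on such
inputs.  No generalized suffix array (multi-record FASTA is
concatenated without separators, so suffixes span records — documented
loudly in the io module).  No multiway merge, no external-memory
variant, no actual thread pool in this implementation.
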