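"""Pivot oversampling keeps samplesort partitions balanced.

With sampling factor s = ceil(32 ln n), the p-1 evenly spaced pivots
taken from the s*p sorted samples keep every partition below a small
constant multiple of n/p with high probability.  This script measures
the worst partition across seeds on random DNA.
"""

import math

import numpy as np

import capssa as cs

n, p = 100_000, 16
s = math.ceil(32 * math.log(n))
print(f"random DNA, n={n}, p={p}, s={s}; ideal partition size n/p = {n // p}")
worst = 0
for seed in range(10):
    text = cs.random_dna(n, seed=seed)
    _, _, stats = cs.construct(text, cs.BuildConfig(p=p, s=s, seed=seed))
    sizes = stats.partition_sizes
    worst = max(worst, int(sizes.max()))
    print(f"  seed {seed}: max partition {int(sizes.max()):>6}  "
          f"(x{sizes.max() / (n / p):.2f} of ideal)")
print(f"\nworst across seeds: {worst}  — bound 3n/p = {3 * n // p}")
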