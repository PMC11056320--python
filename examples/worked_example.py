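"""Build the suffix array and LCP array of a tiny text and print the
classic index table.

Each row i shows SA[i] (the start of the i-th smallest suffix), LCP[i]
(symbols shared with the previous suffix), and the suffix itself.
"""

import capssa as cs

text = cs.build_text("AACTGCGGAT", terminator="$")
sa, lcp, stats = cs.construct(text, cs.BuildConfig(p=2, s=2))

print(f"T = {text}   (n = {text.n})")
print(f"{'i':>3} {'SA':>3} {'LCP':>4}  suffix")
for i, (s, l) in enumerate(zip(sa, lcp)):
    print(f"{i:>3} {s:>3} {l:>4}  {str(text)[s:]}")
print(f"\nsymbol comparisons: {stats.matching} matching, "
      f"{stats.mismatching} mismatching")
print("(at p=1 the matching count equals the LCP sum exactly:",
      f"sum LCP = {int(lcp.sum())})")
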