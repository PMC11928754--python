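"""Find the unique multiMUM of the built-in three-sequence toy instance.

Builds the enhanced generalized suffix array of ABCA, BCAC, ABCD, lists
its lcp-intervals and applies the multiMUM test: a qualifying interval has
width m = 3 (one row per sequence), pairwise-distinct document-array
values (the match is unique in every sequence) and BWT values that are not
all equal (the match cannot be extended left in all sequences at once).
"""

import numpy as np

from panmum import build_gsa, enumerate_lcp_intervals, find_multimums, toy_instance

docs = toy_instance()
print("sequences:", docs)

gsa = build_gsa(docs)
print(f"GSA rows n = {gsa.n} (m + total symbols = 3 + 12)")

print("\nlcp-intervals (ell, [lb..rb]):")
for iv in enumerate_lcp_intervals(gsa):
    das = gsa.da[iv.lb : iv.rb + 1]
    print(f"  {iv.ell}-[{iv.lb}..{iv.rb}]  width={iv.width}  documents={das + 1}")

(mm,) = find_multimums(gsa)
one_based = tuple(p + 1 for p in mm.positions)
print(f"\nunique multiMUM: length={mm.length}, 1-based starts={one_based}")
word = docs[0][mm.positions[0] : mm.positions[0] + mm.length]
print(f"matched substring: {word!r} -- occurs exactly once in each sequence")
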