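"""Evaluate the five block-diversity measures on one haplotype interval.

Builds a small phased sample in which the first four sites are conserved
(two common patterns) and the last two are shuffled, then prints each
diversity on the conserved block and on the full interval.
"""

import numpy as np

import hapseg as hs

rows = [
    "010100",
    "010111",
    "010101",
    "101010",
    "101001",
    "101010",
    "010110",
    "101000",
]
code = {"0": 0, "1": 1}
mat = hs.HaplotypeMatrix(np.array([[code[c] for c in r] for r in rows], dtype=np.int8))

for (i, j) in [(1, 4), (1, 6)]:
    print(f"interval [{i}, {j}]:")
    print(f"  pair-mismatch  dd = {hs.delta_d(mat, i, j):.4f}")
    print(f"  entropy (bits) de = {hs.delta_e(mat, i, j):.4f}")
    print(f"  singletons     dc = {hs.delta_c(mat, i, j):.4f}")
    print(f"  1 - min|D'|   dl1 = {hs.delta_l1(mat, i, j):.4f}")
    print(f"  weak-LD pairs dl2 = {hs.delta_l2(mat, i, j, 0.8):.4f}")

# dc = 0 on [1,4] means every haplotype lies in a common (size >= 2) pattern,
# so [1,4] is a feasible block at the usual limit D = 0.2; appending the two
# shuffled sites turns most rows into singletons and the interval infeasible.
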