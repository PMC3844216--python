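"""Minimum tag-SNP selection, and why tag count is not monotone in length.

Uses the engineered 8 x 4 sample where the 3-site block [1,3] needs three
tag SNPs but the containing 4-site block [1,4] needs only two: the fourth
column turns two haplotypes ambiguous, they merge out of the 80% coverage
selection, and the remaining three patterns separate on two columns.
"""

import hapseg as hs

mat = hs.fig3_case()
print("sample rows:")
for r in mat.row_strings(1, 4):
    print(" ", r)

for (i, j) in [(1, 3), (1, 4)]:
    groups = hs.group_compatible(mat, i, j)
    chosen = hs.select_groups(groups, 0.2)
    res = hs.min_tag_snps(chosen, i, j)
    print(
        f"block [{i},{j}]: {len(groups)} pattern groups, "
        f"{len(chosen)} selected for 80% coverage, "
        f"{res.n_tags} tag SNPs at sites {list(res.tag_loci)}"
    )

# The longer block needs FEWER tags: block length and tagging cost are not
# monotonically related, which is why the budget DP must consider every
# feasible block rather than only maximal ones.
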