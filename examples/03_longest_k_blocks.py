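"""Longest-k-blocks: cover as many SNPs as possible with k disjoint blocks.

Generates a 20-haplotype sample with three planted 10-SNP blocks (three
founder patterns each, reshuffled at the boundaries) and partitions it with
the linear-space divide-and-conquer for increasing k.
"""

import hapseg as hs

spec = hs.FixtureSpec(
    m=20, block_lengths=(10, 10, 10), patterns_per_block=3, missing_rate=0.05, seed=11
)
mat = hs.generate(spec)
print(f"sample: {mat.m} haplotypes x {mat.n} SNPs, planted boundaries after "
      f"sites {spec.boundaries}")

index = hs.build_index(mat, hs.get_diversity("dc"), limit=0.2)
for k in (1, 2, 3, 4):
    res = hs.longest_k_blocks(index, k)
    blocks = ", ".join(f"[{b.start},{b.end}]" for b in res.segmentation.blocks)
    print(
        f"k={k}: covered {res.segmentation.total_length}/{mat.n} SNPs "
        f"with {res.k_used} blocks: {blocks}"
    )

# Each added block extends the covered length; blocks may legitimately
# straddle a planted boundary while the merged pattern spectrum still keeps
# the singleton fraction under the 0.2 limit.
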