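"""Summary artifacts: block-size tables, coverage curves, uninformative markers.

"Genome region covered" is measured in SNP sites (a fraction of n), matching
the SNP-count arithmetic of block partitioning itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .budget import hbpts, max_cover_lengths
from .feasibility import FeasibilityIndex
from .matrix import Segmentation

#: Block-size categories by number of SNPs: label -> (lo, hi) inclusive.
SIZE_CATEGORIES = {">10": (11, None), "3-10": (3, 10), "<3": (1, 2)}


def block_stats(seg: Segmentation, n_sites: int | None = None) -> pd.DataFrame:
    """Per-size-category block table with a totals row.

    Columns: block counts, blocks needing >= 1 tag SNP, block frequency (%)
    and SNP frequency (%).  SNP frequency is relative to the covered sites
    unless ``n_sites`` is given.
    """
    denom_sites = n_sites if n_sites else max(seg.total_length, 1)
    n_blocks = max(len(seg.blocks), 1)
    rows = []
    for label, (lo, hi) in SIZE_CATEGORIES.items():
        blocks = [
            b for b in seg.blocks if b.length >= lo and (hi is None or b.length <= hi)
        ]
        snps = sum(b.length for b in blocks)
        rows.append(
            {
                "category": label,
                "n_blocks": len(blocks),
                "n_blocks_with_tags": sum(1 for b in blocks if b.n_tags >= 1),
                "block_freq_pct": 100.0 * len(blocks) / n_blocks,
                "snp_freq_pct": 100.0 * snps / denom_sites,
            }
        )
    total = {
        "category": "total",
        "n_blocks": sum(r["n_blocks"] for r in rows),
        "n_blocks_with_tags": sum(r["n_blocks_with_tags"] for r in rows),
        "block_freq_pct": sum(r["block_freq_pct"] for r in rows),
        "snp_freq_pct": sum(r["snp_freq_pct"] for r in rows),
    }
    if not seg.blocks:
        for r in rows + [total]:
            r["block_freq_pct"] = 0.0
            r["snp_freq_pct"] = 0.0
    return pd.DataFrame(rows + [total]).set_index("category")


@dataclass(frozen=True)
class CoverageCurvePoint:
    tags_allowed: int
    covered_fraction: float
    zero_tag_blocks: int
    nonzero_tag_blocks: int
    mean_len_nonzero: float


def coverage_curve(
    index: FeasibilityIndex, budgets: list[int], n: int | None = None
) -> list[CoverageCurvePoint]:
    """One optimal segmentation per tag budget, summarized.

    ``budgets`` must be sorted ascending; the covered fraction is
    nondecreasing along the curve (monotone in the budget).
    """
    if budgets != sorted(budgets):
        raise ValueError("budgets must be sorted ascending")
    n = index.n if n is None else n
    points = []
    for t in budgets:
        res = hbpts(index, 1, n, t)
        seg = res.segmentation
        zero = sum(1 for b in seg.blocks if b.n_tags == 0)
        nonzero = [b for b in seg.blocks if b.n_tags > 0]
        points.append(
            CoverageCurvePoint(
                tags_allowed=t,
                covered_fraction=seg.total_length / n,
                zero_tag_blocks=zero,
                nonzero_tag_blocks=len(nonzero),
                mean_len_nonzero=(
                    sum(b.length for b in nonzero) / len(nonzero) if nonzero else 0.0
                ),
            )
        )
    return points


def min_tags_for_coverage(
    index: FeasibilityIndex, target_fraction: float, n: int | None = None
) -> int | None:
    """Smallest tag budget whose optimal cover reaches the target fraction.

    Uses the monotonicity of coverage in the budget; returns None when even
    an unbounded budget cannot reach the target.
    """
    n = index.n if n is None else n
    t0 = max(1, index.t0())
    lengths = max_cover_lengths(index, 1, n, t0 * n)
    need = target_fraction * n
    for t, length in enumerate(lengths):
        if length >= need - 1e-9:
            return t
    return None


def uninformative_markers(index: FeasibilityIndex, n: int | None = None) -> list[int]:
    """Sites inside feasible blocks that require zero tag SNPs.

    These loci sit in stretches where at least ``1 - limit`` of the
    unambiguous haplotypes share a single pattern, so genotyping them adds
    no information about the common variation.
    """
    n = index.n if n is None else n
    sites: set[int] = set()
    for x, i in index.iter_blocks():
        if index.tag_cost(x, i) == 0:
            sites.update(range(x, i + 1))
    return sorted(s for s in sites if s <= n)
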