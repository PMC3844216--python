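"""Longest-blocks-t-tags: maximize covered length under a tag-SNP budget.

The value function ``f(i, j, t)`` is the maximum total length of disjoint
feasible blocks inside ``[i, j]`` whose tag-SNP costs sum to at most ``t``:

    f(i, j', tau) = max( f(i, j'-1, tau),
                         max_{x in L_j', tag(x,j') <= tau}
                             f(i, x-1, tau - tag(x, j')) + (j' - x + 1) )

HBPTS recovers an optimal segmentation in O(L + t0*n) working space, where
``t0`` is the maximum tag cost over all feasible blocks (computed from the
index, never assumed):  when the budget is small (t < 5*t0 + 10) the direct
DP with traceback is used; otherwise the range is cut at a point x* with a
budget split t*, found by scanning x* over all sites and t* over an O(t0)
window around t/2, and both halves are solved recursively.

The split window is ``[floor(t/2) - t0, floor(t/2) + floor(t0/2)]``: an
optimal segmentation's prefix tag sums step by at most t0, so some block
boundary has prefix cost in ``(floor(t/2) - t0, floor(t/2)]``, and when the
budget is tight (no slack) t* must be allowed to sit that far below t/2.
A symmetric window of half-width floor(t0/2) can miss such optima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._space import METER, drop, new_array
from .errors import PartialCoverError, TaggingInfeasibleError
from .feasibility import FeasibilityIndex
from .matrix import Block, Segmentation
from .tagging import tag_block


@dataclass
class BudgetResult:
    segmentation: Segmentation
    tags_used: int
    per_block_tags: list[int] = field(default_factory=list)


def _block_choices(index: FeasibilityIndex, site: int, lo: int):
    """(x, cost) for every taggable feasible block [x, site] with x >= lo."""
    for x in index.feasible_lefts(site, lo):
        c = index.tag_cost(x, site)
        if c is not None:
            yield x, c


def budget_dp_base(index: FeasibilityIndex, i: int, j: int, t: int) -> list[list[int]]:
    """Direct DP table ``f[p][tau]`` for prefixes of ``[i, j]``.

    ``p`` indexes the prefix ending at site ``i + p - 1`` (p = 0 is empty);
    ``tau`` ranges 0..t.  Only used when t is small (the HBPTS base case),
    so the table stays O(n * t0).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    width = j - i + 2
    f = [new_array(t + 1) for _ in range(width)]
    for p in range(1, width):
        site = i + p - 1
        row = f[p]
        prev_row = f[p - 1]
        for tau in range(t + 1):
            best = prev_row[tau]
            for x, c in _block_choices(index, site, i):
                if c <= tau:
                    cand = f[x - i][tau - c] + (site - x + 1)
                    if cand > best:
                        best = cand
            row[tau] = best
    return f


def _base_traceback(index: FeasibilityIndex, i: int, j: int, t: int) -> list[tuple[int, int, int]]:
    """Blocks (start, end, cost) achieving f(i, j, t), via the direct table.

    Deterministic tie rules: skipping the rightmost site is preferred when it
    loses nothing, and among equal-value last blocks the longest (smallest
    start) wins.
    """
    if i > j:
        return []
    f = budget_dp_base(index, i, j, t)
    out: list[tuple[int, int, int]] = []
    p, tau = j - i + 1, t
    while p > 0:
        if f[p][tau] == f[p - 1][tau]:
            p -= 1
            continue
        site = i + p - 1
        chosen = None
        for x, c in sorted(_block_choices(index, site, i)):
            if c <= tau and f[x - i][tau - c] + (site - x + 1) == f[p][tau]:
                chosen = (x, site, c)
                break
        assert chosen is not None, "traceback lost the optimum"
        out.append(chosen)
        p = chosen[0] - i
        tau -= chosen[2]
    for row in f:
        drop(row)
    return sorted(out)


def _forward_layers(index: FeasibilityIndex, i: int, j: int, keep_lo: int, keep_hi: int, t0: int):
    """f(i, x, tau) arrays for tau in [keep_lo, keep_hi], x = i-1..j.

    Layers are computed for tau = 0..keep_hi with only the last t0+1 kept
    live (plus the requested window), so the pass uses O(t0 * n) cells.
    """
    width = j - i + 2
    rolling: dict[int, list[int]] = {}
    kept: dict[int, list[int]] = {}
    for tau in range(keep_hi + 1):
        layer = new_array(width)
        for x in range(i, j + 1):
            p = x - i + 1
            best = layer[p - 1]
            for s, c in _block_choices(index, x, i):
                if c <= tau:
                    src = layer if c == 0 else rolling[tau - c]
                    cand = src[s - i] + (x - s + 1)
                    if cand > best:
                        best = cand
            layer[p] = best
        rolling[tau] = layer
        stale = tau - t0 - 1
        if stale in rolling:
            old = rolling.pop(stale)
            if stale not in kept:
                drop(old)
        if keep_lo <= tau <= keep_hi:
            kept[tau] = layer
    for tau, layer in list(rolling.items()):
        if tau not in kept:
            drop(layer)
    return kept


def _backward_layers(index: FeasibilityIndex, i: int, j: int, keep_lo: int, keep_hi: int, t0: int):
    """f(x, j, tau) arrays for tau in [keep_lo, keep_hi], x = i..j+1."""
    width = j - i + 2
    rolling: dict[int, list[int]] = {}
    kept: dict[int, list[int]] = {}
    for tau in range(keep_hi + 1):
        layer = new_array(width)
        for x in range(j, i - 1, -1):
            p = x - i
            best = layer[p + 1]
            for e in index.feasible_rights(x, j):
                c = index.tag_cost(x, e)
                if c is not None and c <= tau:
                    src = layer if c == 0 else rolling[tau - c]
                    cand = src[e - i + 1] + (e - x + 1)
                    if cand > best:
                        best = cand
            layer[p] = best
        rolling[tau] = layer
        stale = tau - t0 - 1
        if stale in rolling:
            old = rolling.pop(stale)
            if stale not in kept:
                drop(old)
        if keep_lo <= tau <= keep_hi:
            kept[tau] = layer
    for tau, layer in list(rolling.items()):
        if tau not in kept:
            drop(layer)
    return kept


def _hbpts_recurse(
    index: FeasibilityIndex, i: int, j: int, t: int, t0: int, out: list[tuple[int, int, int]]
) -> None:
    if i > j:
        return
    if t < 5 * t0 + 10:
        out.extend(_base_traceback(index, i, j, t))
        return
    half = t // 2
    w_lo = max(0, half - t0)
    w_hi = min(t, half + t0 // 2)
    fwd = _forward_layers(index, i, j, w_lo, w_hi, t0)
    bwd = _backward_layers(index, i, j, t - w_hi, t - w_lo, t0)
    mid = (i + j) // 2
    best = None  # (value, -dist_to_mid, -t_star, -x) maximized
    for t_star in range(w_lo, w_hi + 1):
        a = fwd[t_star]
        b = bwd[t - t_star]
        for x in range(i - 1, j + 1):
            val = a[x - i + 1] + b[x - i + 1]
            key = (val, -abs(x - mid), -t_star, -x)
            if best is None or key > best[0]:
                best = (key, x, t_star)
    for layer in fwd.values():
        drop(layer)
    for layer in bwd.values():
        drop(layer)
    assert best is not None
    _, x_star, t_star = best
    _hbpts_recurse(index, i, x_star, t_star, t0, out)
    _hbpts_recurse(index, x_star + 1, j, t - t_star, t0, out)


def _dress(index: FeasibilityIndex, intervals: list[tuple[int, int, int]]) -> BudgetResult:
    blocks = []
    for s, e, c in sorted(intervals):
        div = index.diversity_of(s, e)
        try:
            loci = list(tag_block(index.mat, s, e, index.limit, index.t_max).tag_loci)
        except TaggingInfeasibleError:  # pragma: no cover - excluded from index
            loci = []
        blocks.append(Block(start=s, end=e, diversity=div, n_tags=len(loci), tag_loci=loci))
    seg = Segmentation(blocks)
    return BudgetResult(
        segmentation=seg,
        tags_used=seg.total_tags,
        per_block_tags=[b.n_tags for b in seg.blocks],
    )


def hbpts(index: FeasibilityIndex, i: int, j: int, t: int, t0: int | None = None) -> BudgetResult:
    """Optimal segmentation of ``[i, j]`` under tag budget ``t`` (HBPTS).

    The recovered segmentation's total length equals the direct DP value
    exactly; working space stays O(t0 * n) plus the output list.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t0 is None:
        t0 = index.t0()
    METER.reset()
    intervals: list[tuple[int, int, int]] = []
    _hbpts_recurse(index, i, j, t, t0, intervals)
    return _dress(index, intervals)


def max_cover_lengths(index: FeasibilityIndex, i: int, j: int, t_cap: int) -> list[int]:
    """Value-only sweep: best covered length for every budget 0..t_cap.

    A single forward pass per budget layer with rolling storage; stops early
    once full cover of ``[i, j]`` is reached (remaining budgets repeat the
    full length).
    """
    t0 = index.t0()
    width = j - i + 2
    full = j - i + 1
    rolling: dict[int, list[int]] = {}
    lengths: list[int] = []
    for tau in range(t_cap + 1):
        layer = new_array(width)
        for x in range(i, j + 1):
            p = x - i + 1
            best = layer[p - 1]
            for s, c in _block_choices(index, x, i):
                if c <= tau:
                    src = layer if c == 0 else rolling[tau - c]
                    cand = src[s - i] + (x - s + 1)
                    if cand > best:
                        best = cand
            layer[p] = best
        rolling[tau] = layer
        stale = tau - t0 - 1
        if stale in rolling:
            drop(rolling.pop(stale))
        lengths.append(layer[full])
        if layer[full] == full:
            lengths.extend([full] * (t_cap - tau))
            break
    for layer in rolling.values():
        drop(layer)
    return lengths


def full_partition_min_tags(index: FeasibilityIndex, n: int | None = None) -> BudgetResult:
    """Cover every site with feasible blocks using the fewest tag SNPs.

    Searches the smallest budget t whose optimal covered length equals n
    (coverage is monotone in t), then recovers that segmentation with HBPTS.
    Raises :class:`PartialCoverError` when no full cover exists.
    """
    if n is None:
        n = index.n
    t0 = index.t0()
    t_cap = max(1, t0) * n  # any segmentation has at most n blocks of cost <= t0
    lengths = max_cover_lengths(index, 1, n, t_cap)
    t_min = next((t for t, length in enumerate(lengths) if length == n), None)
    if t_min is None:
        in_some_block = set()
        for x, i in index.iter_blocks():
            if index.tag_cost(x, i) is not None:
                in_some_block.update(range(x, i + 1))
        uncovered = [s for s in range(1, n + 1) if s not in in_some_block]
        if not uncovered:
            best = hbpts(index, 1, n, t_cap)
            covered = set(best.segmentation.covered_sites())
            uncovered = [s for s in range(1, n + 1) if s not in covered]
        raise PartialCoverError(
            f"no full cover by feasible blocks exists; {len(uncovered)} sites uncoverable",
            uncovered,
        )
    return hbpts(index, 1, n, t_min)
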