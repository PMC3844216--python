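"""Brute-force reference implementations, used only by tests.

These enumerate every disjoint feasible-interval family (for the two
partitioning problems) or the full power set of site subsets (for tag
selection).  They deliberately share no code with the production dynamic
programs and refuse inputs beyond a hard budget, so an accidental
exponential run cannot stall the suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

from .diversity import DiversityFunction
from .errors import (
    IntervalError,
    OracleBudgetError,
    TaggingInfeasibleError,
    UndefinedDiversityError,
)
from .matrix import HaplotypeMatrix
from .tagging import PatternGroup, tag_block


@dataclass(frozen=True)
class OracleBudget:
    max_n: int = 14
    max_k: int = 4
    max_t: int = 6
    max_block_sites_for_tags: int = 12


BUDGET = OracleBudget()


def _feasible_intervals(
    mat: HaplotypeMatrix, delta: DiversityFunction, limit: float
) -> list[tuple[int, int]]:
    out = []
    for i in range(1, mat.n + 1):
        for j in range(i, mat.n + 1):
            try:
                if delta(mat, i, j) <= limit:
                    out.append((i, j))
            except (UndefinedDiversityError, IntervalError):
                continue
    return out


def _max_disjoint(
    intervals: list[tuple[int, int, int]], k: int | None, t: int | None
) -> int:
    """Max total length over disjoint families, optionally capped in count/cost.

    ``intervals`` carries (start, end, cost); recursion over intervals sorted
    by start with memoization on (index, k_left, t_left).
    """
    items = sorted(intervals)
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(idx: int, k_left: int, t_left: int) -> int:
        if idx == len(items) or k_left == 0:
            return 0
        s, e, c = items[idx]
        best = go(idx + 1, k_left, t_left)
        if c <= t_left:
            nxt = idx + 1
            while nxt < len(items) and items[nxt][0] <= e:
                nxt += 1
            best = max(best, (e - s + 1) + go(nxt, k_left - 1, t_left - c))
        return best

    return go(0, len(items) if k is None else k, 10**9 if t is None else t)


def best_k_segmentation_bruteforce(
    mat: HaplotypeMatrix, delta: DiversityFunction, limit: float, k: int
) -> int:
    """Max total length over all families of <= k disjoint feasible intervals."""
    if mat.n > BUDGET.max_n or k > BUDGET.max_k:
        raise OracleBudgetError(f"n={mat.n}, k={k} beyond oracle budget")
    feas = [(i, j, 0) for i, j in _feasible_intervals(mat, delta, limit)]
    return _max_disjoint(feas, k, None)


def best_budget_segmentation_bruteforce(
    mat: HaplotypeMatrix,
    delta: DiversityFunction,
    limit: float,
    t: int,
    t_max: int = 8,
) -> int:
    """Max total length over disjoint feasible families with tag-cost sum <= t."""
    if mat.n > BUDGET.max_n or t > BUDGET.max_t:
        raise OracleBudgetError(f"n={mat.n}, t={t} beyond oracle budget")
    feas = []
    for i, j in _feasible_intervals(mat, delta, limit):
        try:
            cost = tag_block(mat, i, j, limit, t_max).n_tags
        except TaggingInfeasibleError:
            continue
        feas.append((i, j, cost))
    return _max_disjoint(feas, None, t)


def min_tags_bruteforce(selected: list[PatternGroup], i: int, j: int) -> int:
    """Minimum distinguishing site-subset size by full power-set scan."""
    width = j - i + 1
    if width > BUDGET.max_block_sites_for_tags:
        raise OracleBudgetError(f"{width} sites beyond oracle tag budget")
    consensi = [g.consensus for g in selected]
    if len(consensi) <= 1:
        return 0
    if len(set(consensi)) < len(consensi):
        raise TaggingInfeasibleError("identical consensi cannot be distinguished")
    for subset in chain.from_iterable(
        combinations(range(width), r) for r in range(width + 1)
    ):
        if len({tuple(c[p] for p in subset) for c in consensi}) == len(consensi):
            return len(subset)
    raise TaggingInfeasibleError("no distinguishing subset exists")  # pragma: no cover
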