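"""Feasible-block preprocessing for the partitioning dynamic programs.

For a diversity function delta and limit D, a block ``[x, i]`` is *feasible*
when ``delta(x, i) <= D`` (undefined diversity counts as infeasible).  Two
index flavours are built:

* **monotonic** — for monotonic diversity functions a single left *good
  partner* ``L[i]`` (the farthest feasible left endpoint) and its mirror
  ``R[i]`` fully describe the feasible blocks ending/starting at each site;
  both arrays come from an O(n) two-pointer sweep.
* **general** — with a nonmonotonic function (``dc`` on missing data) the
  feasible left endpoints of a site can have holes, so the full sets ``L_i``
  are enumerated, truncated at a maximum block width ``W``.

Tag costs ``tag(x, i)`` are memoized per feasible block; a block whose tag
search exceeds ``t_max`` is dropped from the index (with a logged warning)
rather than stalling the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .diversity import DiversityFunction, effectively_monotonic
from .errors import IntervalError, UndefinedDiversityError
from .matrix import MISSING, HaplotypeMatrix
from .tagging import DEFAULT_T_MAX, tag_block
from .errors import TaggingInfeasibleError

log = logging.getLogger(__name__)

DEFAULT_MAX_WIDTH = 300

_DROPPED = -1  # sentinel in the tag-cost memo for untaggable blocks


@dataclass
class FeasibilityIndex:
    """Preprocessed feasible blocks (and lazily their tag costs)."""

    mat: HaplotypeMatrix
    delta: DiversityFunction
    limit: float
    mode: str  # "monotonic" | "general"
    max_width: int
    t_max: int = DEFAULT_T_MAX
    left: list[int | None] = field(default_factory=list)  # L[i], index 1..n
    right: list[int | None] = field(default_factory=list)  # R[i]
    left_sets: list[list[int]] = field(default_factory=list)  # general mode L_i
    right_sets: list[list[int]] = field(default_factory=list)  # derived: R_x
    _tag_memo: dict[tuple[int, int], int] = field(default_factory=dict)
    _t0: int | None = None

    @property
    def n(self) -> int:
        return self.mat.n

    # -- feasible-block enumeration -------------------------------------

    def feasible_lefts(self, i: int, lo: int = 1) -> list[int]:
        """Feasible left endpoints x >= lo of blocks ending at site ``i``."""
        if self.mode == "general":
            return [x for x in self.left_sets[i] if x >= lo]
        L = self.left[i]
        if L is None:
            return []
        return list(range(max(L, lo, i - self.max_width + 1), i + 1))

    def feasible_rights(self, x: int, hi: int | None = None) -> list[int]:
        """Feasible right endpoints j <= hi of blocks starting at site ``x``."""
        hi = self.n if hi is None else hi
        if self.mode == "general":
            return [j for j in self.right_sets[x] if j <= hi]
        R = self.right[x]
        if R is None:
            return []
        return list(range(x, min(R, hi, x + self.max_width - 1) + 1))

    def good_partner(self, i: int, lo: int = 1) -> int | None:
        """Farthest feasible left endpoint >= lo for a block ending at ``i``.

        In monotonic mode this is the clipped good partner; in general mode
        the smallest member of ``L_i`` at or past ``lo``.
        """
        lefts = self.feasible_lefts(i, lo)
        return lefts[0] if lefts else None

    def iter_blocks(self):
        """All feasible blocks (x, i) in the index."""
        for i in range(1, self.n + 1):
            for x in self.feasible_lefts(i):
                yield x, i

    # -- tag-cost cache ---------------------------------------------------

    def tag_cost(self, x: int, i: int) -> int | None:
        """Tag-SNP cost of feasible block ``[x, i]``; None if untaggable."""
        key = (x, i)
        cached = self._tag_memo.get(key)
        if cached is None:
            try:
                cached = tag_block(self.mat, x, i, self.limit, self.t_max).n_tags
            except TaggingInfeasibleError:
                log.warning("block [%d, %d] dropped: no tag set of size <= %d", x, i, self.t_max)
                cached = _DROPPED
            self._tag_memo[key] = cached
        return None if cached == _DROPPED else cached

    def t0(self) -> int:
        """Maximum tag cost over all feasible blocks (computed, not assumed)."""
        if self._t0 is None:
            best = 0
            for x, i in self.iter_blocks():
                c = self.tag_cost(x, i)
                if c is not None and c > best:
                    best = c
            self._t0 = best
        return self._t0

    def diversity_of(self, x: int, i: int) -> float:
        return self.delta(self.mat, x, i)


def _feasible(delta: DiversityFunction, mat: HaplotypeMatrix, x: int, i: int, D: float) -> bool:
    try:
        return delta(mat, x, i) <= D
    except (UndefinedDiversityError, IntervalError):
        return False


def build_monotonic_index(
    mat: HaplotypeMatrix,
    delta: DiversityFunction,
    limit: float,
    max_width: int = DEFAULT_MAX_WIDTH,
    t_max: int = DEFAULT_T_MAX,
) -> FeasibilityIndex:
    """Two-pointer good-partner sweep for a monotonic diversity function.

    ``L[i]`` is the smallest x with ``delta(x, i) <= limit``; monotonicity
    makes L nondecreasing in i, so the left pointer never backs up.  Sites
    where even ``[i, i]`` is infeasible get ``L[i] = None``.
    """
    n = mat.n
    left: list[int | None] = [None] * (n + 1)
    x = 1
    for i in range(1, n + 1):
        if x > i:
            x = i
        while x <= i and not _feasible(delta, mat, x, i, limit):
            x += 1
        left[i] = x if x <= i else None

    right: list[int | None] = [None] * (n + 2)
    y = n
    for i in range(n, 0, -1):
        if y < i:
            y = i
        while y >= i and not _feasible(delta, mat, i, y, limit):
            y -= 1
        right[i] = y if y >= i else None

    return FeasibilityIndex(
        mat=mat, delta=delta, limit=limit, mode="monotonic",
        max_width=max_width, t_max=t_max, left=left, right=right,
    )


def _scan_left_spectrum(mat: HaplotypeMatrix, i: int, width: int, kind: str):
    """Yield (x, diversity) for x = i, i-1, ... by incremental refinement.

    Extending the interval leftward only refines the pattern groups (new
    group id = (old id, new allele)) and permanently ambiguates rows that
    are missing at the added column, so each step costs O(m).
    """
    import numpy as np

    m = mat.m
    gid = [0] * m  # group id per row; -1 = ambiguous
    col_cache = mat.alleles
    lo = max(1, i - width + 1)
    for x in range(i, lo - 1, -1):
        col = col_cache[:, x - 1]
        fresh: dict[tuple[int, int], int] = {}
        for r in range(m):
            if gid[r] < 0:
                continue
            a = int(col[r])
            if a == MISSING:
                gid[r] = -1
                continue
            key = (gid[r], a)
            nid = fresh.get(key)
            if nid is None:
                nid = len(fresh)
                fresh[key] = nid
            gid[r] = nid
        sizes: dict[int, int] = {}
        n_unamb = 0
        for g in gid:
            if g >= 0:
                sizes[g] = sizes.get(g, 0) + 1
                n_unamb += 1
        if n_unamb == 0:
            yield x, None
            continue
        if kind == "dc":
            val = sum(1 for c in sizes.values() if c == 1) / n_unamb
        elif kind == "dd":
            val = 1.0 - sum((c / n_unamb) ** 2 for c in sizes.values())
        else:  # de
            val = -sum(
                (c / n_unamb) * np.log2(c / n_unamb) for c in sizes.values()
            )
        yield x, float(val)


def build_general_index(
    mat: HaplotypeMatrix,
    delta: DiversityFunction,
    limit: float,
    max_width: int = DEFAULT_MAX_WIDTH,
    t_max: int = DEFAULT_T_MAX,
    precompute_tags: bool = True,
) -> FeasibilityIndex:
    """Enumerate every feasible left endpoint set ``L_i`` up to width ``W``.

    Works for any diversity function; the spectrum-based measures (dd, de,
    dc) use an incremental leftward scan so each candidate block costs O(m).
    With ``precompute_tags`` the tag cost of every feasible block is filled
    eagerly (the budget DP needs them all anyway).
    """
    n = mat.n
    left_sets: list[list[int]] = [[] for _ in range(n + 1)]
    spectrum_kinds = ("dd", "de", "dc")
    for i in range(1, n + 1):
        if delta.name in spectrum_kinds:
            for x, val in _scan_left_spectrum(mat, i, max_width, delta.name):
                if val is not None and val <= limit:
                    left_sets[i].append(x)
        else:
            for x in range(i, max(1, i - max_width + 1) - 1, -1):
                if _feasible(delta, mat, x, i, limit):
                    left_sets[i].append(x)
        left_sets[i].sort()

    right_sets: list[list[int]] = [[] for _ in range(n + 2)]
    for i in range(1, n + 1):
        for x in left_sets[i]:
            right_sets[x].append(i)
    for x in range(1, n + 1):
        right_sets[x].sort()

    index = FeasibilityIndex(
        mat=mat, delta=delta, limit=limit, mode="general",
        max_width=max_width, t_max=t_max,
        left_sets=left_sets, right_sets=right_sets,
    )
    if precompute_tags:
        dropped = []
        for x, i in list(index.iter_blocks()):
            if index.tag_cost(x, i) is None:
                dropped.append((x, i))
        for x, i in dropped:
            left_sets[i].remove(x)
            right_sets[x].remove(i)
    return index


def build_index(
    mat: HaplotypeMatrix,
    delta: DiversityFunction,
    limit: float,
    max_width: int = DEFAULT_MAX_WIDTH,
    t_max: int = DEFAULT_T_MAX,
) -> FeasibilityIndex:
    """Pick the monotonic or general build automatically for this matrix."""
    if effectively_monotonic(delta, mat):
        return build_monotonic_index(mat, delta, limit, max_width, t_max)
    return build_general_index(mat, delta, limit, max_width, t_max)
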