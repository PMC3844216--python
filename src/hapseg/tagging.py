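"""Minimum tag-SNP selection within a block (a MINIMUM TEST SET search).

The pipeline for a block ``[i, j]`` is:

1. :func:`group_compatible` — group the block's haplotypes into patterns,
   merging ambiguous (missing-data) rows into compatible groups and assigning
   missing entries by within-group majority;
2. :func:`select_groups` — pick the fewest groups whose unambiguous members
   reach coverage ``1 - D`` of the block's unambiguous haplotypes;
3. :func:`min_tag_snps` — find the smallest site subset whose projection
   makes the selected groups' consensus patterns pairwise distinct, by
   enumerating t-combinations in lexicographic order for t = 0, 1, 2, ...

Finding the minimum distinguishing set is NP-complete in general, but the
required tag count stays small in practice, so the exhaustive search is
bounded by ``t_max`` (default 8) and a block whose search exceeds it is
declared untaggable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from .errors import TaggingInfeasibleError
from .matrix import MAJOR, MISSING, HaplotypeMatrix, check_interval

DEFAULT_T_MAX = 8


@dataclass
class PatternGroup:
    """A merged class of compatible haplotypes with its consensus pattern."""

    consensus: str  # '0'/'1' (and '?' only while still under construction)
    members: list[int] = field(default_factory=list)  # 1-based row indices
    n_unambiguous_members: int = 0


def _compatible(row: str, consensus: str) -> bool:
    """Rows are compatible when they agree wherever both are non-missing."""
    return all(a == b or a == "?" or b == "?" for a, b in zip(row, consensus))


def group_compatible(mat: HaplotypeMatrix, i: int, j: int) -> list[PatternGroup]:
    """Group the rows of ``[i, j]`` into patterns, merging ambiguous rows.

    Unambiguous rows are first grouped by identity.  Each ambiguous row is
    then merged into the compatible group with the most unambiguous members
    (ties broken by lexicographically smallest consensus); rows compatible
    with no existing group seed their own.  Finally every consensus is
    completed by per-site majority vote among members (fully-missing columns
    fall back to the major allele).
    """
    check_interval(i, j, mat.n)
    rows = mat.row_strings(i, j)
    groups: list[PatternGroup] = []
    by_consensus: dict[str, PatternGroup] = {}
    ambiguous_rows: list[int] = []
    for r, row in enumerate(rows, start=1):
        if "?" in row:
            ambiguous_rows.append(r)
            continue
        g = by_consensus.get(row)
        if g is None:
            g = PatternGroup(consensus=row)
            by_consensus[row] = g
            groups.append(g)
        g.members.append(r)
        g.n_unambiguous_members += 1

    for r in ambiguous_rows:
        row = rows[r - 1]
        candidates = [g for g in groups if _compatible(row, g.consensus)]
        if candidates:
            # largest unambiguous membership first, then smallest consensus
            best = min(candidates, key=lambda g: (-g.n_unambiguous_members, g.consensus))
            best.members.append(r)
        else:
            g = PatternGroup(consensus=row, members=[r])
            groups.append(g)

    for g in groups:
        g.consensus = _finalize_consensus(g, rows)
    return groups


def _finalize_consensus(group: PatternGroup, rows: list[str]) -> str:
    width = len(group.consensus)
    out = []
    for c in range(width):
        votes = Counter(rows[r - 1][c] for r in group.members)
        votes.pop("?", None)
        if not votes:
            out.append("0" if MAJOR == 0 else "1")  # fully-missing column
            continue
        top = max(votes.values())
        # majority allele; exact tie falls back to the major allele '0'
        winners = sorted(a for a, v in votes.items() if v == top)
        out.append(winners[0])
    return "".join(out)


def select_groups(groups: list[PatternGroup], limit: float) -> list[PatternGroup]:
    """Shortest prefix of groups covering >= ``1 - limit`` unambiguous rows.

    Groups are ranked by unambiguous membership (descending, ties by
    lexicographically smallest consensus), so the greedy prefix is minimal
    in group count.  The coverage boundary is inclusive.
    """
    total = sum(g.n_unambiguous_members for g in groups)
    if total < 1:
        raise TaggingInfeasibleError("no unambiguous haplotypes to cover")
    ranked = sorted(groups, key=lambda g: (-g.n_unambiguous_members, g.consensus))
    need = (1.0 - limit) * total
    covered = 0
    chosen: list[PatternGroup] = []
    for g in ranked:
        if covered >= need and chosen:
            break
        chosen.append(g)
        covered += g.n_unambiguous_members
    # guard against float fuzz on exact boundaries such as 4/5 == 80%
    while len(chosen) > 1 and (covered - chosen[-1].n_unambiguous_members) * 1.0 >= need - 1e-9:
        covered -= chosen[-1].n_unambiguous_members
        chosen.pop()
    return chosen


@dataclass(frozen=True)
class TagSearchResult:
    """Outcome of the minimum tag-SNP search for one block."""

    tag_loci: tuple[int, ...]  # sorted 1-based site indices
    n_groups_distinguished: int
    coverage: float

    @property
    def n_tags(self) -> int:
        return len(self.tag_loci)


def min_tag_snps(
    selected: list[PatternGroup],
    i: int,
    j: int,
    t_max: int = DEFAULT_T_MAX,
    coverage: float = 1.0,
) -> TagSearchResult:
    """Smallest site set of ``[i, j]`` distinguishing the selected consensi.

    Candidate t-combinations are enumerated in lexicographic order, so the
    returned set is deterministic and of true minimum cardinality.  Raises
    :class:`TaggingInfeasibleError` when no set of size <= ``t_max`` works
    (e.g. two selected groups share a consensus).
    """
    if not selected:
        raise TaggingInfeasibleError("no groups selected")
    k = len(selected)
    if k == 1:
        return TagSearchResult((), 1, coverage)
    consensi = [g.consensus for g in selected]
    width = j - i + 1
    if len(set(consensi)) < k:
        raise TaggingInfeasibleError("two selected groups share an identical consensus")
    # t binary tags split patterns into at most 2**t classes
    t_start = max(1, (k - 1).bit_length())
    for t in range(t_start, min(t_max, width) + 1):
        for combo in combinations(range(width), t):
            projections = {tuple(c[p] for p in combo) for c in consensi}
            if len(projections) == k:
                return TagSearchResult(tuple(i + p for p in combo), k, coverage)
    raise TaggingInfeasibleError(
        f"no tag set of size <= {min(t_max, width)} distinguishes {k} patterns in [{i}, {j}]"
    )


def tag_block(
    mat: HaplotypeMatrix,
    i: int,
    j: int,
    limit: float = 0.2,
    t_max: int = DEFAULT_T_MAX,
) -> TagSearchResult:
    """Full tag-selection pipeline for block ``[i, j]`` at diversity limit D."""
    groups = group_compatible(mat, i, j)
    total = sum(g.n_unambiguous_members for g in groups)
    chosen = select_groups(groups, limit)
    covered = sum(g.n_unambiguous_members for g in chosen)
    coverage = covered / total if total else 0.0
    return min_tag_snps(chosen, i, j, t_max=t_max, coverage=coverage)
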