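import pytest

import hapseg as hs
from hapseg._space import METER
from hapseg.budget import budget_dp_base, max_cover_lengths
from hapseg.diversity import DiversityFunction
from hapseg.feasibility import FeasibilityIndex
from hapseg.oracles import best_budget_segmentation_bruteforce
from hapseg.tagging import tag_block
from hapseg.errors import TaggingInfeasibleError


def make_index(seed, missing_rate=0.0, m=8, n=12, limit=0.2):
    mat = hs.random_matrix(m, n, missing_rate=missing_rate, seed=seed)
    return mat, hs.build_index(mat, hs.get_diversity("dc"), limit)


def synthetic_index(n, blocks):
    """Hand-crafted index: ``blocks`` maps (start, end) -> tag cost.

    Lets DP-layer tests pin exact block/cost structure independently of any
    diversity function (diversity_of reports 0 for dressing).
    """
    mat = hs.random_matrix(2, n, seed=0)
    left_sets = [[] for _ in range(n + 1)]
    right_sets = [[] for _ in range(n + 2)]
    for (s, e) in blocks:
        left_sets[e].append(s)
        right_sets[s].append(e)
    for ls in left_sets:
        ls.sort()
    for rs in right_sets:
        rs.sort()
    idx = FeasibilityIndex(
        mat=mat,
        delta=DiversityFunction("stub", lambda m_, i, j: 0.0, monotonic_claim=False),
        limit=0.2,
        mode="general",
        max_width=n,
        left_sets=left_sets,
        right_sets=right_sets,
    )
    idx._tag_memo = {k: v for k, v in blocks.items()}
    return idx


# ---- base DP ---------------------------------------------------------------


def test_budget_zero_uses_only_free_blocks():
    idx = synthetic_index(6, {(1, 2): 0, (3, 4): 1, (5, 6): 0})
    f = budget_dp_base(idx, 1, 6, 3)
    assert f[6][0] == 4  # the two free blocks
    assert f[6][1] == 6


def test_budget_at_least_full_cover_cost_reaches_n():
    mat, idx = make_index(21, missing_rate=0.1)
    lengths = max_cover_lengths(idx, 1, mat.n, max(1, idx.t0()) * mat.n)
    if mat.n in lengths:
        t_full = lengths.index(mat.n)
        assert budget_dp_base(idx, 1, mat.n, t_full + 3)[mat.n][t_full + 3] == mat.n


@pytest.mark.parametrize("seed", range(15))
def test_base_dp_matches_bruteforce(seed):
    mat, idx = make_index(seed, missing_rate=0.1 if seed % 2 else 0.0)
    f = budget_dp_base(idx, 1, mat.n, 5)
    for t in range(6):
        want = best_budget_segmentation_bruteforce(mat, idx.delta, idx.limit, t)
        assert f[mat.n][t] == want


def test_value_monotone_in_budget_and_saturates():
    mat, idx = make_index(33, missing_rate=0.05)
    cap = max(1, idx.t0()) * mat.n
    lengths = max_cover_lengths(idx, 1, mat.n, cap)
    assert all(a <= b for a, b in zip(lengths, lengths[1:]))
    # unconstrained optimum equals the k-unbounded block cover
    f = hs.longest_k_blocks_table(idx, mat.n)
    assert lengths[-1] == f[mat.n][mat.n]


# ---- HBPTS -----------------------------------------------------------------


@pytest.mark.parametrize("seed", range(15))
def test_hbpts_equals_base_dp_small_budgets(seed):
    mat, idx = make_index(seed + 50, missing_rate=0.1 if seed % 2 else 0.0)
    f = budget_dp_base(idx, 1, mat.n, 6)
    for t in range(7):
        res = hs.hbpts(idx, 1, mat.n, t)
        assert res.segmentation.total_length == f[mat.n][t]
        assert res.tags_used <= t
        assert res.per_block_tags == [b.n_tags for b in res.segmentation.blocks]


@pytest.mark.parametrize("seed", range(4))
def test_hbpts_divide_branch_matches_base_dp(seed):
    """Budgets above 5*t0+10 force at least one divide-and-conquer level."""
    mat = hs.random_matrix(10, 40, missing_rate=0.0, seed=90 + seed)
    idx = hs.build_index(mat, hs.get_diversity("dc"), 0.2)
    t0 = idx.t0()
    for t in (5 * t0 + 10, 5 * t0 + 17):
        res = hs.hbpts(idx, 1, mat.n, t)
        assert res.segmentation.total_length == budget_dp_base(idx, 1, mat.n, t)[mat.n][t]


def test_hbpts_window_search_beats_naive_half_split():
    """A costly block straddling the midpoint defeats a fixed t* = t//2 split."""
    idx = synthetic_index(8, {(1, 2): 1, (3, 6): 2, (7, 8): 1})
    t = 4
    full = budget_dp_base(idx, 1, 8, t)[8][t]
    assert full == 8
    half = t // 2
    naive = 0
    for x in range(0, 9):
        a = budget_dp_base(idx, 1, x, half)[x][half] if x >= 1 else 0
        b = budget_dp_base(idx, x + 1, 8, t - half)[8 - x][t - half] if x < 8 else 0
        naive = max(naive, a + b)
    assert naive < full
    assert hs.hbpts(idx, 1, 8, t).segmentation.total_length == full


def test_hbpts_recovery_space_stays_in_t0_window():
    """No t x n table outside the rolling t0 window during recovery."""
    mat = hs.random_matrix(10, 60, missing_rate=0.0, seed=91)
    idx = hs.build_index(mat, hs.get_diversity("dc"), 0.2)
    t0 = idx.t0()
    t = max(60, 8 * t0 + 16)
    res = hs.hbpts(idx, 1, mat.n, t)
    peak = METER.peak_cells
    n = mat.n
    bound = 6 * (t0 + 2) * (n + 2) + (5 * t0 + 11) * (n + 2)
    assert peak <= bound
    assert peak < (t + 1) * n  # far below a full t x n table
    assert res.segmentation.total_length == max_cover_lengths(idx, 1, n, t)[-1]


# ---- full partition --------------------------------------------------------


def test_repeated_row_matrix_partitions_free(strings_matrix):
    mat = strings_matrix(["0101"] * 6)
    idx = hs.build_index(mat, hs.get_diversity("dc"), 0.2)
    res = hs.full_partition_min_tags(idx)
    assert res.tags_used == 0
    assert [(b.start, b.end) for b in res.segmentation.blocks] == [(1, 4)]


def brute_full_min_tags(mat, delta, limit):
    from functools import lru_cache

    feas = {}
    for i in range(1, mat.n + 1):
        for j in range(i, mat.n + 1):
            try:
                if delta(mat, i, j) <= limit:
                    feas[(i, j)] = tag_block(mat, i, j, limit).n_tags
            except (hs.UndefinedDiversityError, TaggingInfeasibleError):
                continue

    @lru_cache(maxsize=None)
    def go(pos):
        if pos > mat.n:
            return 0
        best = None
        for (i, j), c in feas.items():
            if i == pos:
                sub = go(j + 1)
                if sub is not None:
                    cand = c + sub
                    best = cand if best is None or cand < best else best
        return best

    return go(1)


@pytest.mark.parametrize("seed", range(12))
def test_full_partition_reaches_bruteforce_minimum_tags(seed):
    mat, idx = make_index(seed + 70, missing_rate=0.1 if seed % 2 else 0.0, n=10)
    want = brute_full_min_tags(mat, idx.delta, idx.limit)
    if want is None:
        with pytest.raises(hs.PartialCoverError):
            hs.full_partition_min_tags(idx)
        return
    res = hs.full_partition_min_tags(idx)
    assert res.segmentation.total_length == mat.n
    assert res.tags_used == want


def test_full_partition_block_count_consistent_with_k_blocks():
    """On monotone complete data the partition's block count is the smallest
    k whose k-block optimum already covers every site."""
    mat = hs.random_matrix(8, 12, missing_rate=0.0, seed=44)
    idx = hs.build_index(mat, hs.get_diversity("dc"), 0.2)
    try:
        res = hs.full_partition_min_tags(idx)
    except hs.PartialCoverError:
        pytest.skip("no full cover on this fixture")
    f = hs.longest_k_blocks_table(idx, mat.n)
    k_min = next(k for k in range(1, mat.n + 1) if f[k][mat.n] == mat.n)
    assert len(res.segmentation.blocks) >= k_min
    # and a k_min-block cover exists, so the partition covers with >= k_min blocks
    assert f[k_min][mat.n] == mat.n


def test_partial_cover_lists_uncoverable_sites():
    idx = synthetic_index(5, {(1, 2): 0, (4, 5): 1})  # site 3 in no block
    with pytest.raises(hs.PartialCoverError) as exc:
        hs.full_partition_min_tags(idx)
    assert exc.value.uncovered_sites == [3]
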