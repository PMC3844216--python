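import itertools

import numpy as np
import pytest

import hapseg as hs
from hapseg import MISSING, UndefinedDiversityError, UndefinedLDError
from hapseg.diversity import _d_prime_or_none


# ---- independent oracles ---------------------------------------------------


def pair_mismatch_oracle(mat, i, j):
    """Fraction of ordered row pairs (with replacement) that differ."""
    rows = [r for r in mat.row_strings(i, j) if "?" not in r]
    pairs = [(a, b) for a in rows for b in rows]
    return sum(a != b for a, b in pairs) / len(pairs)


def entropy_oracle(mat, i, j):
    rows = [r for r in mat.row_strings(i, j) if "?" not in r]
    total = len(rows)
    return -sum(
        (rows.count(p) / total) * np.log2(rows.count(p) / total) for p in set(rows)
    )


def d_prime_oracle(mat, a, b):
    """Contingency-table |D'|: D = p11 - p1.p.1, Dmax by the standard min rule."""
    xs = mat.alleles[:, a - 1]
    ys = mat.alleles[:, b - 1]
    keep = (xs != MISSING) & (ys != MISSING)
    xs, ys = xs[keep], ys[keep]
    n = len(xs)
    p1 = (xs == 1).sum() / n
    q1 = (ys == 1).sum() / n
    p11 = ((xs == 1) & (ys == 1)).sum() / n
    d = p11 - p1 * q1
    dmax = min(p1 * (1 - q1), (1 - p1) * q1) if d >= 0 else min(p1 * q1, (1 - p1) * (1 - q1))
    return abs(d) / dmax


# ---- spectrum --------------------------------------------------------------


def test_spectrum_counts_identical_rows(all_identical):
    spec = hs.spectrum(all_identical, 1, 4)
    assert spec.counts == (4,)
    assert spec.n_ambiguous == 0


def test_spectrum_excludes_ambiguous_rows(strings_matrix):
    mat = strings_matrix(["00", "00", "0?"])
    spec = hs.spectrum(mat, 1, 2)
    assert spec.counts == (2,)
    assert spec.n_ambiguous == 1


def test_spectrum_conserves_rows_over_all_intervals():
    mat = hs.random_matrix(10, 8, missing_rate=0.15, seed=11)
    for i in range(1, 9):
        for j in range(i, 9):
            spec = hs.spectrum(mat, i, j)
            assert sum(spec.counts) + spec.n_ambiguous == 10
            assert sum(spec.counts) == spec.n_unambiguous


# ---- dd / de / dc ----------------------------------------------------------


def test_delta_d_frozen_examples(all_identical, all_distinct):
    assert hs.delta_d(all_identical, 1, 4) == 0.0
    assert hs.delta_d(all_distinct, 1, 3) == pytest.approx(0.75)


def test_delta_d_counts_221_matches_pair_enumeration(strings_matrix):
    mat = strings_matrix(["00", "00", "01", "10"])  # counts {2,1,1}
    assert hs.delta_d(mat, 1, 2) == pytest.approx(0.625)
    assert hs.delta_d(mat, 1, 2) == pytest.approx(pair_mismatch_oracle(mat, 1, 2))


def test_delta_d_matches_oracle_on_all_intervals():
    mat = hs.random_matrix(8, 7, missing_rate=0.1, seed=5)
    for i in range(1, 8):
        for j in range(i, 8):
            spec = hs.spectrum(mat, i, j)
            if spec.n_unambiguous == 0:
                continue
            assert hs.delta_d(mat, i, j) == pytest.approx(
                pair_mismatch_oracle(mat, i, j), abs=1e-12
            )


def test_delta_e_frozen_examples(all_identical, strings_matrix):
    assert hs.delta_e(all_identical, 1, 4) == 0.0
    two_groups = strings_matrix(["00", "00", "11", "11"])
    assert hs.delta_e(two_groups, 1, 2) == pytest.approx(1.0)
    mat = strings_matrix(["00", "00", "01", "10"])  # counts {2,1,1} -> 1.5 bits
    assert hs.delta_e(mat, 1, 2) == pytest.approx(1.5)
    assert hs.delta_e(mat, 1, 2) == pytest.approx(entropy_oracle(mat, 1, 2))


def test_delta_c_feasible_and_infeasible_coverage_cases(strings_matrix):
    # 10 unambiguous rows, 9 in common groups -> diversity 0.1 (feasible)
    feasible = strings_matrix(["000"] * 5 + ["011"] * 4 + ["110"])
    assert hs.delta_c(feasible, 1, 3) == pytest.approx(1 / 10)
    # 7 unambiguous rows, only 3 common -> 4/7 (infeasible at D=0.2)
    infeasible = strings_matrix(["000"] * 3 + ["011", "101", "110", "111"])
    assert hs.delta_c(infeasible, 1, 3) == pytest.approx(4 / 7)
    assert hs.delta_c(strings_matrix(["01"] * 6), 1, 2) == 0.0


def test_delta_c_plus_coverage_is_one_on_every_interval():
    mat = hs.random_matrix(9, 8, missing_rate=0.1, seed=3)
    for i in range(1, 9):
        for j in range(i, 9):
            if hs.spectrum(mat, i, j).n_unambiguous == 0:
                continue
            assert hs.delta_c(mat, i, j) + hs.common_coverage(mat, i, j) == pytest.approx(1.0)


def test_zero_unambiguous_rows_is_undefined(strings_matrix):
    mat = strings_matrix(["?0", "?1"])
    for fn in (hs.delta_d, hs.delta_e, hs.delta_c):
        with pytest.raises(UndefinedDiversityError):
            fn(mat, 1, 1)


def test_dd_de_monotone_on_complete_data():
    """Subintervals never exceed the parent's dd/de diversity (complete data)."""
    mat = hs.random_matrix(10, 12, missing_rate=0.0, seed=17)
    for fn in (hs.delta_d, hs.delta_e):
        vals = {
            (i, j): fn(mat, i, j)
            for i in range(1, 13)
            for j in range(i, 13)
        }
        for (i, j), v in vals.items():
            for i2 in range(i, j + 1):
                for j2 in range(i2, j + 1):
                    assert vals[(i2, j2)] <= v + 1e-12


def test_dc_nonmonotonic_only_with_missing_data():
    mat = hs.nonmonotonic_case()
    assert hs.delta_c(mat, 1, 8) <= 0.2
    violations = [x for x in range(2, 9) if hs.delta_c(mat, x, 8) > 0.2]
    assert violations, "a subinterval should exceed the limit the superinterval meets"
    # completing the missing entries restores monotonicity
    complete = hs.HaplotypeMatrix(np.where(mat.alleles == MISSING, 0, mat.alleles))
    vals = {
        (i, j): hs.delta_c(complete, i, j) for i in range(1, 9) for j in range(i, 9)
    }
    for (i, j), v in vals.items():
        for i2 in range(i, j + 1):
            for j2 in range(i2, j + 1):
                assert vals[(i2, j2)] <= v + 1e-12


def test_dd_stays_monotone_on_nonmonotonic_case_fixture():
    mat = hs.nonmonotonic_case()
    vals = {}
    for i in range(1, 9):
        for j in range(i, 9):
            if hs.spectrum(mat, i, j).n_unambiguous >= 1:
                vals[(i, j)] = hs.delta_d(mat, i, j)
    for (i, j), v in vals.items():
        for (i2, j2), v2 in vals.items():
            if i <= i2 and j2 <= j:
                assert v2 <= v + 1e-12


# ---- LD-based measures -----------------------------------------------------


def test_d_prime_frozen_examples(strings_matrix):
    coupled = strings_matrix(["11", "11", "00", "00"])
    assert hs.d_prime(coupled, 1, 2) == pytest.approx(1.0)
    equilibrium = strings_matrix(["00", "01", "10", "11"])
    assert hs.d_prime(equilibrium, 1, 2) == pytest.approx(0.0)


def test_d_prime_matches_contingency_oracle():
    mat = hs.random_matrix(20, 2, missing_rate=0.0, seed=23)
    assert hs.d_prime(mat, 1, 2) == pytest.approx(d_prime_oracle(mat, 1, 2))


def test_d_prime_undefined_on_monomorphic_site(strings_matrix):
    mat = strings_matrix(["00", "01"])
    with pytest.raises(UndefinedLDError):
        hs.d_prime(mat, 1, 2)


def test_delta_l1_frozen_and_exhaustive():
    coupled = hs.HaplotypeMatrix(np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=np.int8))
    assert hs.delta_l1(coupled, 1, 2) == pytest.approx(0.0)
    eq = hs.HaplotypeMatrix(np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8))
    assert hs.delta_l1(eq, 1, 2) == pytest.approx(1.0)
    mat = hs.random_matrix(12, 8, missing_rate=0.05, seed=9)
    expected = 1.0 - min(
        v
        for a, b in itertools.combinations(range(1, 9), 2)
        if (v := _d_prime_or_none(mat, a, b)) is not None
    )
    assert hs.delta_l1(mat, 1, 8) == pytest.approx(expected)


def test_delta_l2_frozen_and_exhaustive(strings_matrix):
    coupled = strings_matrix(["111", "111", "000", "000"])
    assert hs.delta_l2(coupled, 1, 3, 0.8) == 0.0
    eq = strings_matrix(["00", "01", "10", "11"])
    assert hs.delta_l2(eq, 1, 2, 0.8) == 1.0
    mat = hs.random_matrix(12, 7, missing_rate=0.05, seed=13)
    weak = sum(
        1
        for a, b in itertools.combinations(range(1, 8), 2)
        if (v := _d_prime_or_none(mat, a, b)) is None or v < 0.8
    )
    assert hs.delta_l2(mat, 1, 7, 0.8) == pytest.approx(weak / 21)


def test_registry_names_and_interval_validation():
    for name in hs.DIVERSITY_NAMES:
        fn = hs.get_diversity(name)
        assert fn.name == name
    mat = hs.random_matrix(4, 4, seed=1)
    with pytest.raises(hs.IntervalError):
        hs.spectrum(mat, 3, 2)
    with pytest.raises(hs.IntervalError):
        hs.delta_l1(mat, 2, 2)
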