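"""Block-diversity measures for haplotype intervals.

Five diversity functions are provided, all mapping an interval ``[i, j]`` of a
haplotype matrix to a non-negative real:

``dd``
    Probability that two haplotypes drawn at random (with replacement) from
    the interval's unambiguous rows differ: ``1 - sum p_g**2`` over pattern
    groups.  Monotonic.
``de``
    Shannon entropy (bits) of the pattern-group frequencies.  Monotonic.
``dc``
    Singleton fraction among unambiguous rows, i.e. one minus the
    common-haplotype coverage (a pattern is "common" when >= 2 unambiguous
    rows share it).  NOT monotonic once the sample has missing data: widening
    an interval can ambiguate singleton rows and shrink the denominator.
``dl1``
    One minus the minimum pairwise |D'| over all site pairs in the interval.
``dl2``
    Fraction of site pairs without strong LD (|D'| below a threshold).

Rows carrying a missing entry anywhere inside the interval ("ambiguous" rows)
are excluded from the pattern spectrum of dd/de/dc; an interval with zero
unambiguous rows has undefined diversity and is treated as infeasible by the
preprocessing layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import UndefinedDiversityError, UndefinedLDError
from .matrix import MISSING, HaplotypeMatrix, check_interval, span


@dataclass(frozen=True)
class PatternSpectrum:
    """Multiset of identical-row group sizes over the unambiguous rows."""

    counts: tuple[int, ...]
    n_unambiguous: int
    n_ambiguous: int

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.counts if c == 1)


def spectrum(mat: HaplotypeMatrix, i: int, j: int) -> PatternSpectrum:
    """Group the unambiguous rows of ``[i, j]`` by exact string identity."""
    win = mat.window(i, j)
    ambiguous = (win == MISSING).any(axis=1)
    groups = Counter(map(tuple, win[~ambiguous]))
    counts = tuple(sorted(groups.values(), reverse=True))
    return PatternSpectrum(
        counts=counts,
        n_unambiguous=int((~ambiguous).sum()),
        n_ambiguous=int(ambiguous.sum()),
    )


def _freqs(mat: HaplotypeMatrix, i: int, j: int) -> np.ndarray:
    spec = spectrum(mat, i, j)
    if spec.n_unambiguous == 0:
        raise UndefinedDiversityError(
            f"no unambiguous haplotypes in [{i}, {j}]; diversity undefined"
        )
    return np.array(spec.counts, dtype=float) / spec.n_unambiguous


def delta_d(mat: HaplotypeMatrix, i: int, j: int) -> float:
    """Probability two random unambiguous haplotypes of ``[i, j]`` differ."""
    p = _freqs(mat, i, j)
    return float(1.0 - np.sum(p * p))


def delta_e(mat: HaplotypeMatrix, i: int, j: int) -> float:
    """Shannon entropy (bits) of the pattern frequencies of ``[i, j]``."""
    p = _freqs(mat, i, j)
    return float(-np.sum(p * np.log2(p)))


def delta_c(mat: HaplotypeMatrix, i: int, j: int) -> float:
    """Singleton share of the unambiguous rows (1 - common coverage)."""
    spec = spectrum(mat, i, j)
    if spec.n_unambiguous == 0:
        raise UndefinedDiversityError(
            f"no unambiguous haplotypes in [{i}, {j}]; diversity undefined"
        )
    return spec.n_singletons / spec.n_unambiguous


def common_coverage(mat: HaplotypeMatrix, i: int, j: int) -> float:
    """Fraction of unambiguous rows lying in common (size >= 2) groups."""
    return 1.0 - delta_c(mat, i, j)


def _d_prime_or_none(mat: HaplotypeMatrix, a: int, b: int) -> float | None:
    """|D'| for sites a, b over rows complete at both loci, or None if undefined."""
    check_interval(a, a, mat.n)
    check_interval(b, b, mat.n)
    xa = mat.alleles[:, a - 1]
    xb = mat.alleles[:, b - 1]
    keep = (xa != MISSING) & (xb != MISSING)
    if not keep.any():
        return None
    xa, xb = xa[keep], xb[keep]
    n = xa.shape[0]
    pa = float(np.mean(xa == 1))
    pb = float(np.mean(xb == 1))
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None  # monomorphic in the pairwise-complete subset
    p11 = float(np.sum((xa == 1) & (xb == 1))) / n
    d = p11 - pa * pb
    if d >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    return abs(d) / d_max


def d_prime(mat: HaplotypeMatrix, a: int, b: int) -> float:
    """Normalized LD |D'| in [0, 1] between sites ``a`` and ``b``.

    Raises :class:`UndefinedLDError` when either locus is monomorphic (or
    completely missing) within the pairwise-complete row subset.
    """
    val = _d_prime_or_none(mat, a, b)
    if val is None:
        raise UndefinedLDError(f"|D'| undefined for site pair ({a}, {b})")
    return val


def delta_l1(mat: HaplotypeMatrix, i: int, j: int) -> float:
    """One minus the minimum pairwise |D'| over all site pairs of ``[i, j]``.

    Pairs with undefined |D'| are skipped; if every pair is undefined the
    diversity itself is undefined.
    """
    check_interval(i, j, mat.n, strict=True)
    best: float | None = None
    for a in range(i, j + 1):
        for b in range(a + 1, j + 1):
            v = _d_prime_or_none(mat, a, b)
            if v is not None and (best is None or v < best):
                best = v
    if best is None:
        raise UndefinedDiversityError(f"all |D'| pairs undefined in [{i}, {j}]")
    return 1.0 - best


def delta_l2(
    mat: HaplotypeMatrix, i: int, j: int, strong_ld_threshold: float = 0.8
) -> float:
    """Fraction of site pairs of ``[i, j]`` without strong LD.

    A pair is "without strong LD" when |D'| < ``strong_ld_threshold``;
    undefined pairs count as without strong LD (conservative).
    """
    check_interval(i, j, mat.n, strict=True)
    width = span(i, j)
    n_pairs = width * (width - 1) // 2
    weak = 0
    for a in range(i, j + 1):
        for b in range(a + 1, j + 1):
            v = _d_prime_or_none(mat, a, b)
            if v is None or v < strong_ld_threshold:
                weak += 1
    return weak / n_pairs


@dataclass(frozen=True)
class DiversityFunction:
    """A named diversity measure with its monotonicity contract.

    ``monotonic_claim`` states whether subintervals are guaranteed never to
    exceed the parent interval's diversity.  ``dc`` is monotonic only on
    complete data; use :func:`effectively_monotonic` to decide per matrix.
    """

    name: str
    evaluate: Callable[[HaplotypeMatrix, int, int], float] = field(repr=False)
    monotonic_claim: bool
    limit_default: float = 0.2
    strong_ld_threshold: float | None = None

    def __call__(self, mat: HaplotypeMatrix, i: int, j: int) -> float:
        return self.evaluate(mat, i, j)


def get_diversity(name: str, strong_ld_threshold: float = 0.8) -> DiversityFunction:
    """Look up a diversity function by name (``dd, de, dc, dl1, dl2``)."""
    if name == "dd":
        return DiversityFunction("dd", delta_d, monotonic_claim=True)
    if name == "de":
        return DiversityFunction("de", delta_e, monotonic_claim=True)
    if name == "dc":
        return DiversityFunction("dc", delta_c, monotonic_claim=False)
    if name == "dl1":
        return DiversityFunction("dl1", delta_l1, monotonic_claim=True)
    if name == "dl2":
        return DiversityFunction(
            "dl2",
            lambda mat, i, j: delta_l2(mat, i, j, strong_ld_threshold),
            monotonic_claim=False,
            strong_ld_threshold=strong_ld_threshold,
        )
    raise ValueError(f"unknown diversity function {name!r}")


DIVERSITY_NAMES = ("dd", "de", "dc", "dl1", "dl2")


def effectively_monotonic(fn: DiversityFunction, mat: HaplotypeMatrix) -> bool:
    """Whether ``fn`` can be trusted monotonic on this particular matrix.

    The spectrum measures (dd, de, dc) are monotonic on complete data, where
    widening an interval only refines the pattern groups.  Once rows carry
    missing entries the ambiguous-row exclusion rule lets widening *remove*
    rows from the spectrum, which can lower any of the three, so only the
    general (set-valued) feasibility scan is safe.  ``dl1`` stays monotonic
    regardless: each pair's |D'| is fixed and a superinterval only adds
    pairs to the minimum.
    """
    if fn.name in ("dd", "de", "dc"):
        return not (mat.alleles == MISSING).any()
    return fn.name == "dl1"
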