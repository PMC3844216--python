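"""Synthetic haplotype matrices with planted block structure.

The generator emulates the data regime the partitioning algorithms target:
a small panel of phased haplotypes (default 20, the size of the classic
chromosome-21 panel), a few founder haplotype patterns per block with
pattern reshuffling at block boundaries (recombination hotspots), a
per-entry missing-data rate, and a per-site minor-allele frequency of at
least 0.1 enforced by rejection sampling.

Two engineered matrices back the structural counterexamples the algorithms
must handle: :func:`nonmonotonic_case` (missing data makes the singleton
fraction nonmonotonic in interval width) and :func:`fig3_case` (a longer
block can need fewer tag SNPs than a block it contains).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .matrix import MISSING, HaplotypeMatrix


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic matrix."""

    m: int = 20
    block_lengths: tuple[int, ...] = (10, 10, 10)
    patterns_per_block: int = 3
    missing_rate: float = 0.0
    maf_min: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or not self.block_lengths or min(self.block_lengths) < 1:
            raise GenerationError("need m >= 1 and non-empty positive block lengths")
        if not (0.0 <= self.missing_rate < 1.0):
            raise GenerationError("missing_rate must be in [0, 1)")

    @property
    def n(self) -> int:
        return sum(self.block_lengths)

    @property
    def boundaries(self) -> list[int]:
        """Internal planted boundaries as the last site of each block but one."""
        out, acc = [], 0
        for length in self.block_lengths[:-1]:
            acc += length
            out.append(acc)
        return out


_MAX_TRIES = 500


def _draw_block(
    rng: np.random.Generator, m: int, length: int, k: int, maf_min: float
) -> np.ndarray:
    """One block: k distinct founders, rows assigned independently to founders.

    Rejection sampling enforces per-site MAF >= maf_min; with a single
    founder every site is monomorphic, so the constraint is skipped there.
    """
    for _ in range(_MAX_TRIES):
        founders = rng.integers(0, 2, size=(k, length))
        if k > 1 and len({tuple(f) for f in founders}) < k:
            continue
        assignment = rng.integers(0, k, size=m)
        sub = founders[assignment]
        if k > 1:
            minor = np.minimum(sub.sum(axis=0), m - sub.sum(axis=0))
            if (minor < maf_min * m).any():
                continue
        return sub
    raise GenerationError(
        f"could not satisfy MAF >= {maf_min} with m={m}, k={k}, length={length}"
    )


def generate(spec: FixtureSpec) -> HaplotypeMatrix:
    """Generate a matrix from ``spec``; deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    parts = [
        _draw_block(rng, spec.m, length, spec.patterns_per_block, spec.maf_min)
        for length in spec.block_lengths
    ]
    alleles = np.concatenate(parts, axis=1).astype(np.int8)
    if spec.missing_rate > 0:
        mask = rng.random(alleles.shape) < spec.missing_rate
        alleles[mask] = MISSING
    return HaplotypeMatrix(alleles)


def random_matrix(
    m: int, n: int, missing_rate: float = 0.0, seed: int = 0
) -> HaplotypeMatrix:
    """Unstructured i.i.d. matrix (uniform alleles), for property tests."""
    rng = np.random.default_rng(seed)
    alleles = rng.integers(0, 2, size=(m, n)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(alleles.shape) < missing_rate
        alleles[mask] = MISSING
    return HaplotypeMatrix(alleles)


def nonmonotonic_case() -> HaplotypeMatrix:
    """A matrix where the singleton-fraction diversity is nonmonotonic.

    Four rows are distinct singletons on the right-hand interval [3, 8]
    (singleton fraction 4/14 > 0.2, infeasible) but carry missing entries in
    the two left columns, so on the wider interval [1, 8] they become
    ambiguous and drop out of the spectrum: the ten remaining rows pair up
    into five common patterns (singleton fraction 0 <= 0.2, feasible).
    Widening the block thus *lowered* its diversity.

    The ten complete rows are built so the pair-mismatch diversity stays
    monotone on the very same matrix: their five patterns on [1, 8] merge
    into a 6/4 split on [3, 8], which offsets the four returning singletons.
    """
    rows = [
        "00000000",
        "00000000",
        "01000000",
        "01000000",
        "10000000",
        "10000000",
        "00111111",
        "00111111",
        "01111111",
        "01111111",
        "??110000",
        "??001100",
        "??000011",
        "??101010",
    ]
    return _from_strings(rows)


def fig3_case() -> HaplotypeMatrix:
    """A matrix where a 4-site block needs fewer tag SNPs than its 3-site sub-block.

    On [1, 3] the eight rows fall into four equal patterns {000, 001, 010,
    100}; covering 80% needs all four, and every column pair leaves a
    collision, so three tags are required.  On [1, 4] the two ``100?`` rows
    are ambiguous and merge out of the selection; the three selected
    patterns {0000, 0011, 0100} are distinguished by columns 2 and 4 alone.
    """
    rows = [
        "0000",
        "0000",
        "0011",
        "0011",
        "0100",
        "0100",
        "100?",
        "100?",
    ]
    return _from_strings(rows)


def _from_strings(rows: list[str]) -> HaplotypeMatrix:
    code = {"0": 0, "1": 1, "?": MISSING}
    return HaplotypeMatrix(np.array([[code[c] for c in r] for r in rows], dtype=np.int8))
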