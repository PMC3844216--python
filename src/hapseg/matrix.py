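"""Core data containers: phased haplotype matrices, blocks and segmentations.

A haplotype matrix holds ``m`` phased haplotypes (rows) over ``n`` biallelic
SNP sites (columns), coded site-locally as major/minor with an explicit
missing symbol.  All public site indices in this package are **1-based** and
intervals ``[i, j]`` are **inclusive**; this module owns the single helper
that converts to the internal 0-based numpy storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError, IntervalError

#: Allele codes used in the internal int8 storage.
MAJOR: int = 0
MINOR: int = 1
MISSING: int = 2

#: Characters accepted on input for each code ('?' is canonical on output).
_DECODE = {"0": MAJOR, "1": MINOR, "?": MISSING, "2": MISSING, "N": MISSING, "n": MISSING}
_ENCODE = {MAJOR: "0", MINOR: "1", MISSING: "?"}


def span(i: int, j: int) -> int:
    """Number of sites in the inclusive interval ``[i, j]``."""
    return j - i + 1


def check_interval(i: int, j: int, n: int, *, strict: bool = False) -> None:
    """Validate a 1-based inclusive interval against a matrix of ``n`` sites.

    With ``strict=True`` additionally require ``j > i`` (pairwise-LD measures
    need at least two sites).
    """
    if not (1 <= i <= j <= n):
        raise IntervalError(f"invalid interval [{i}, {j}] for n={n}")
    if strict and j == i:
        raise IntervalError(f"interval [{i}, {j}] must contain at least two sites")


@dataclass
class HaplotypeMatrix:
    """An ``m x n`` grid of alleles over {MAJOR, MINOR, MISSING}.

    Parameters
    ----------
    alleles
        int8 array of shape ``(m, n)`` with entries in {0, 1, 2}.
    site_ids
        ``n`` site labels; defaults to ``s1 .. sn``.
    sample_ids
        ``m`` haplotype labels; defaults to ``h1 .. hm``.
    """

    alleles: np.ndarray
    site_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 1 or self.alleles.shape[1] < 1:
            raise ConsistencyError("haplotype matrix must be 2-D with m >= 1, n >= 1")
        if not np.isin(self.alleles, (MAJOR, MINOR, MISSING)).all():
            raise ConsistencyError("allele entries must be MAJOR, MINOR or MISSING")
        m, n = self.alleles.shape
        if not self.site_ids:
            self.site_ids = [f"s{c}" for c in range(1, n + 1)]
        if not self.sample_ids:
            self.sample_ids = [f"h{r}" for r in range(1, m + 1)]
        if len(self.site_ids) != n or len(self.sample_ids) != m:
            raise ConsistencyError("label lengths must match the matrix shape")

    @property
    def m(self) -> int:
        return self.alleles.shape[0]

    @property
    def n(self) -> int:
        return self.alleles.shape[1]

    def window(self, i: int, j: int) -> np.ndarray:
        """0-based view of the columns of the 1-based inclusive interval [i, j]."""
        check_interval(i, j, self.n)
        return self.alleles[:, i - 1 : j]

    def row_strings(self, i: int, j: int) -> list[str]:
        """Rows of ``[i, j]`` as '0'/'1'/'?' strings (one per haplotype)."""
        win = self.window(i, j)
        return ["".join(_ENCODE[int(a)] for a in row) for row in win]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and self.site_ids == other.site_ids
            and self.sample_ids == other.sample_ids
        )


@dataclass
class Block:
    """A 1-based inclusive SNP interval with its diversity and tag SNPs."""

    start: int
    end: int
    diversity: float = 0.0
    n_tags: int = 0
    tag_loci: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConsistencyError(f"block start {self.start} > end {self.end}")
        self.tag_loci = sorted(int(t) for t in self.tag_loci)
        if len(self.tag_loci) != self.n_tags:
            raise ConsistencyError("n_tags must equal len(tag_loci)")
        if any(not (self.start <= t <= self.end) for t in self.tag_loci):
            raise ConsistencyError("tag loci must lie inside the block")
        if self.diversity < 0:
            raise ConsistencyError("diversity must be >= 0")

    @property
    def length(self) -> int:
        return span(self.start, self.end)


@dataclass
class Segmentation:
    """An ordered family of pairwise-disjoint blocks."""

    blocks: list[Block]

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for left, right in zip(self.blocks, self.blocks[1:]):
            if right.start <= left.end:
                raise ConsistencyError(
                    f"blocks [{left.start},{left.end}] and [{right.start},{right.end}] overlap"
                )

    @property
    def total_length(self) -> int:
        return sum(b.length for b in self.blocks)

    @property
    def total_tags(self) -> int:
        return sum(b.n_tags for b in self.blocks)

    def covered_sites(self) -> list[int]:
        out: list[int] = []
        for b in self.blocks:
            out.extend(range(b.start, b.end + 1))
        return out


def decode_symbol(ch: str) -> int:
    try:
        return _DECODE[ch]
    except KeyError:
        raise KeyError(ch) from None


def encode_code(code: int) -> str:
    return _ENCODE[int(code)]
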