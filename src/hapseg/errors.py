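"""Exception hierarchy shared across the package."""


class HapsegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HapsegError):
    """Malformed input file (ragged rows, unknown allele symbol, bad header)."""


class IntervalError(HapsegError):
    """An interval [i, j] violates 1 <= i <= j <= n (or j > i where required)."""


class ConsistencyError(HapsegError):
    """Objects disagree (e.g. a block outside its matrix's site range)."""


class UndefinedDiversityError(HapsegError):
    """Diversity is undefined on the interval (no unambiguous haplotypes).

    Callers in the feasibility layer treat this as "infeasible", never as a
    hard failure.
    """


class UndefinedLDError(UndefinedDiversityError):
    """|D'| is undefined for a site pair (monomorphic in the complete subset)."""


class TaggingInfeasibleError(HapsegError):
    """No tag set of size <= t_max distinguishes the selected patterns."""


class PartialCoverError(HapsegError):
    """A full partition into feasible blocks does not exist."""

    def __init__(self, message: str, uncovered_sites: list[int]):
        super().__init__(message)
        self.uncovered_sites = uncovered_sites


class GenerationError(HapsegError):
    """The synthetic-data generator could not satisfy its constraints."""


class OracleBudgetError(HapsegError):
    """A brute-force oracle was asked to run beyond its hard-coded budget."""
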