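# Methods

This note records the model, the concrete rules chosen where the design was
genuinely open, the numerical conventions, and what the synthetic data does
and does not establish.

## Data model and conventions

A haplotype matrix is an m × n grid over {major, minor, missing}, stored as
int8 (0/1/2). All public site indices are 1-based and intervals [i, j] are
inclusive; a single helper performs the conversion to 0-based storage.
Allele coding is site-local major/minor; multi-allelic VCF records are
rejected at ingestion, and unphased genotypes are an error (the methods
assume phased haplotypes). On input the missing symbols `?`, `2`, `N`, `n`
are all accepted because published haplotype files mix digit and letter
conventions; `?` is canonical on output.

## Diversity of a block

A block's rows are partitioned into pattern groups. Rows with a missing
entry anywhere inside the interval are *ambiguous* and excluded from the
spectrum of the three pattern-based measures (`dd`, `de`, `dc`); an
interval whose rows are all ambiguous has undefined diversity and is simply
infeasible — never an error above the diversity layer. This exclusion rule
is applied uniformly: the singleton-fraction measure is defined over
unambiguous rows by construction, and the pair-mismatch and entropy
measures follow the same rule for consistency (the alternative, wildcard
pattern matching, is used only in tag selection, where ambiguous rows are
explicitly merged into compatible groups).

A consequence worth stating plainly: **all three spectrum measures are
monotonic only on complete data.** Widening an interval can ambiguate rows
out of the spectrum, which may lower any of them. `build_index` therefore
uses the two-pointer good-partner construction only when the matrix has no
missing entries (or for `dl1`, which is monotonic unconditionally: each
pair's |D′| is a constant of the pair, and widening only adds pairs under
the minimum); otherwise it enumerates the feasible-start sets exactly.

Entropy is reported in bits (base 2); the base only rescales the limit
parameter. |D′| is computed from two-locus haplotype frequencies over rows
complete at both sites, with D_max by the standard min rule; a pair is
undefined when either locus is monomorphic in that subset. Undefined pairs
are skipped by `dl1` (its minimum ranges over observed evidence) but
counted as "without strong LD" by `dl2` (conservative: unobservable LD is
not strong LD). The strong-LD threshold defaults to 0.8 and is a required,
explicit parameter of `dl2`.

## Tag SNP selection

For a block [i, j] at diversity limit D (default 0.2):

1. **Grouping.** Unambiguous rows group by string identity. Each ambiguous
   row merges into the compatible group (agreement wherever both are
   non-missing) with the most unambiguous members; ties prefer the
   lexicographically smallest consensus. Rows compatible with nothing seed
   their own group. Merge order is a package rule — results depend on it
   and no canonical order exists — chosen so that larger (better supported)
   groups absorb ambiguous rows first and the outcome is deterministic.
2. **Missing-data assignment.** Each consensus is completed by per-site
   majority vote among members; an exact tie and a fully-missing column
   fall back to the major allele.
3. **Selection.** Groups ranked by unambiguous membership (descending,
   lexicographic tie-break); the shortest prefix reaching coverage ≥ 1 − D
   of the block's unambiguous rows is selected. The boundary is inclusive
   (4 of 5 singleton rows meets an 80% requirement exactly); a small
   epsilon guards the comparison against float error in (1 − D) · total.
4. **Search.** Site t-combinations are enumerated in lexicographic order
   for t = ⌈log₂ k⌉ … t_max (k selected groups can never be separated by
   fewer than ⌈log₂ k⌉ binary tags, so smaller t is skipped soundly). The
   first combination projecting all selected consensi to distinct strings
   is returned — the true minimum, deterministically. If nothing of size
   ≤ t_max (default 8, matching the largest cost observed in practice on
   real panels) works, the block is declared untaggable and dropped from
   the feasibility index with a warning, rather than stalling the run.

Distinguishability is required among the *selected groups' consensi* only:
the selection step already guarantees those groups carry ≥ 1 − D of the
unambiguous haplotypes, so separating them uniquely distinguishes that
share of the sample.

## Feasibility preprocessing

Monotonic case: L[i] (smallest feasible start for a block ending at i) and
R[i] are computed by a two-pointer sweep — monotonicity makes both arrays
monotone, so the sweep is O(n) diversity evaluations. General case: for
each i every start in [i − W + 1, i] is tested with an incremental
leftward scan (extending an interval leftward only refines pattern groups
and permanently ambiguates rows missing at the new column, so each step is
O(m)). The width cap W (default 300) bounds the otherwise quadratic scan;
it comfortably exceeds the largest blocks reported on real chromosome-scale
panels, and any block the cap excludes would be wider than W SNPs.

Tag costs are memoized per feasible block; the general build fills them
eagerly because the budget DP needs every cost anyway. t₀, the maximum tag
cost over feasible blocks, is always computed from the index, never
assumed.

## The two dynamic programs

**Longest k blocks.** Value recurrence as in the README; in the monotonic
case the single good partner suffices (the value function is 1-Lipschitz
in its right endpoint, so the farthest feasible start dominates), in the
general case the inner max ranges over L_j. Boundary recovery is
divide-and-conquer: value-only forward f(⌊k/2⌋, lo, ·) and backward
f(⌈k/2⌉, ·, hi) passes (two rolling 1-D arrays each), a cut x* maximizing
their sum, and recursion into both halves; k = 1 bottoms out by scanning
for the longest feasible block. Ties: smaller cut first, then smaller
block start. Working space is O(n) — asserted structurally in tests via an
allocation meter on the recovery paths, not just claimed.

**Budget DP / HBPTS.** Direct DP over (site, residual budget) with
traceback when t < 5t₀ + 10 (the table is then O(n·t₀)); otherwise the
range is cut at (x*, t*) and both halves solved recursively. The t* search
window is `[⌊t/2⌋ − t₀, ⌊t/2⌋ + ⌊t₀/2⌋]`, deliberately asymmetric: an
optimal segmentation's prefix tag sums step by at most t₀ per block, so
some block boundary has prefix cost in (⌊t/2⌋ − t₀, ⌊t/2⌋], and when the
budget is tight (zero slack) t* must be allowed to sit up to t₀ below
⌊t/2⌋ — a symmetric half-width-⌊t₀/2⌋ window can miss such optima. The
window is still O(t₀) values, and exact equality with the direct DP is
tested on every fixture, including budgets that force multiple recursion
levels. Layer storage keeps a rolling window of t₀ + 1 site-arrays per
pass (costs never exceed t₀), so recovery space is O(t₀·n) plus the
output. Ties among (x*, t*): x* closest to the midpoint, then smallest t*,
then smallest x*. Blocks are not forced contiguous — uncovered gaps are
allowed, since the budget problem maximizes covered length rather than
partitioning.

**Full partition at minimum tags.** A single value-only sweep raises the
budget layer by layer until the optimum covers all n sites (coverage is
monotone in the budget), then HBPTS recovers the segmentation at that
minimum. If the sweep exhausts t₀·n (an upper bound on any segmentation's
cost) without full cover, a partial-cover error lists the sites contained
in no feasible block (or, failing that, the sites the best achievable
cover misses). Traceback prefers skipping sites over starting a block when
the value ties and the longest (smallest-start) last block among ties, so
output is deterministic; among equal-tag optima this tends to fewer,
longer blocks.

Behavior at sites with no feasible block ending there is the first-branch
of the recurrence only (the site is simply skipped); a k (or t) larger
than the data can use is legal and reported via `k_used` (`tags_used`)
rather than an error.

## Synthetic data

The generator plants founder patterns per block: each block draws
`patterns_per_block` distinct founder strings, each row picks a founder
independently per block (reshuffling at boundaries emulates recombination
hotspots), missing entries are masked i.i.d., and rejection sampling
enforces per-site MAF ≥ 0.1 among the assigned alleles (skipped for
single-founder blocks, where every site is necessarily monomorphic).
Defaults mirror the classic chromosome-21 panel regime: m = 20 haplotypes,
MAF ≥ 0.1, a few percent missing calls.

What it does *not* emulate: coalescent genealogy, mutation/recombination
rate variation in physical coordinates, genotyping-error structure, or
correlated founder assignment across blocks (a row switches founders
independently at every boundary, which is more aggressive reshuffling than
real recombination). Passing tests therefore certify the combinatorial
optimality and exactness of the algorithms on block-structured data, not
population-genetic realism. In particular, the full-partition driver
recovers planted boundaries within ±1 site only ~75% of the time under the
default three-block conditions — merging two planted blocks is often
genuinely cheaper in tags, and the objective knows nothing about the
planted truth — so boundary recovery is reported as a rate by the
acceptance script, not asserted.

Two hand-built matrices pin the structural counterexamples: a 14 × 8
sample whose wide interval is feasible (singleton fraction 0) while a
sub-interval is not (4/14), with the complete rows arranged so the
pair-mismatch measure stays monotone on the same matrix; and an 8 × 4
sample whose 3-site block needs 3 tags while the containing 4-site block
needs 2. Both are verified exhaustively in tests (full interval scans,
power-set tag oracle).

## Oracles and problem sizes

Brute-force references (exhaustive disjoint-family enumeration, power-set
tag search) are independent implementations with hard budgets (n ≤ 14,
k ≤ 4, t ≤ 6, ≤ 12 sites for tag oracles). The test suite runs both DPs
against them on 50+ randomized fixtures (m ≤ 10, n ≤ 14, missing rate 0 or
0.1) and the tag search on every feasible block of ≤ 12 sites across
fixture batches. The acceptance script uses a 20 × 288 sample (24 planted
12-SNP blocks) for the full-partition metrics and 100 three-block samples
for boundary recovery; these sizes keep a full from-scratch run within a
few seconds while exercising every code path, including the
divide-and-conquer branches.

## Known limitations

- Biallelic SNPs only; multi-allelic sites are rejected, not split.
- The exhaustive tag search is exponential in the tag count by design
  (exactness is the point); t_max caps the damage and drops pathological
  blocks instead of approximating.
- The general feasibility scan is O(n·W·m); W protects against quadratic
  blowup but silently truncates blocks wider than W.
- Coverage accounting is in SNP sites, not physical base pairs.
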