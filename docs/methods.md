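# Methods

## The problem

UPGMA builds a rooted ultrametric tree by repeatedly merging the two
clusters at minimal distance and updating distances with the size-weighted
arithmetic mean (Lance–Williams with coefficients |i|/(|i|+|j|),
|j|/(|i|+|j|), 0, 0), which equals the mean distance over all element
pairs.  When the minimum is attained by more than one pair — a *tie in
proximity* — the binary result depends on an arbitrary choice.  Ties are
not numerical accidents: proximity values are stated at a finite number of
decimal digits p, and the fewer digits (and the fewer alleles per
microsatellite locus), the more often two pairs collide exactly.  This
package treats p as part of the data and makes every consequence of a tie
explicit: the tie log, the unique multidendrogram, and the exact count of
alternative binary dendrograms.

## Distances from genotypes

For individuals a, b and ploidy r, the proportion of shared alleles at one
locus is `Σ_alleles min(count_a, count_b) / r`, averaged over the loci typed
in both individuals (pairwise-complete; a pair sharing no typed locus is an
error rather than an imputed value).  The per-locus formula follows the
standard shared-allele definition; duplicate alleles count via multiset
overlap, so {1,1} vs {1,2} shares one allele, not two.  Similarities map to
distances by `1 − s` (keeps the decimal precision exactly) or `−ln s`
(irrational, hence marked unrounded; s = 0 is an error unless the caller
supplies a finite cap — no principled default exists).  One case in the
motivating literature quotes shared-allele distances ranging up to 2, which
matches neither transform; both are supported and neither is guessed.

## Precision and exact arithmetic

`precision_p` is inferred from the printed tokens (maximum digits after the
decimal point, trailing zeros included).  Rounding is half-away-from-zero
on decimal digits — the convention of printed tables — and is monotone and
idempotent.  Asymmetric input beyond half a printed unit is rejected, never
averaged.  Printed precision above 12 digits is treated as unrounded (it is
a float `repr`, not a stated resolution).

Internally every clustering engine converts the matrix to exact rationals
(`fractions.Fraction`): p-decimal inputs become k/10^p exactly, and the
weighted-mean update is computed without floating error.  This matters: a
working mean can land exactly on a rounding half (e.g. 0.65 at p = 1), and
float summation order would then decide the rounded value, making merge
commutation order-dependent and the dendrogram count irreproducible.  With
rationals, the working distance of a cluster pair depends only on the
clusters' composition, never on merge order.

Two rounding regimes are implemented (`reround` flag).  Default ON: the
minimum, the tie set and the merge heights are read from the working
distances *re-rounded to p* after every update, so ties deep in the tree
are judged at the same resolution as the input.  OFF: exact working values
are compared, so only input-level collisions tie.  Which regime surveyed
software uses is generally undocumented; ON is the default because the
stated resolution of the data is the only resolution the analyst ever saw.
Note the update itself always propagates the exact (unrounded) means — the
rounded values are a *view* — so heights are reproducible functions of the
clade composition.

## Pair-group UPGMA and the tie log

Clusters are indexed in creation order (merged clusters appended last); the
tie rule picks the lexicographically first (default, mimicking common
software) or last tied index pair.  Every step emits a record with the
minimal distance, all tied pairs and the chosen pair; a clustering "has
ties" iff some step had ≥ 2 tied pairs.  Node height is the (rounded)
merge distance; heights are non-decreasing root-ward because average-link
updates never fall below the current minimum and rounding is monotone.

## Multidendrogram and tie bands

The variable-group variant merges, in one step, every connected component
of the graph whose edges are the tied pairs (if B ties with A and with C,
all three fuse even if d(A,C) is larger).  The node's height and band
minimum equal the rounded minimal distance; the band maximum is the largest
*unrounded* pairwise working distance among the fused clusters, displayed
at p decimals.  A two-cluster merge has a degenerate band; in the rare case
where rounding puts the unrounded maximum marginally below the height, the
band is clamped so band_min ≤ band_max.  The construction involves no
choices, so the result is invariant under input relabeling — the property
that motivates it.

## Enumeration

"Structurally different" means different canonical form: leaves by label,
children sorted lexicographically, heights printed at p decimals (so
topology *and* heights distinguish trees; a topology-only mode is a flag).
The optimized counter runs depth-first over tie choices, memoizing states
keyed by the sorted multiset of subtree canonical forms: two orders of
commuting merges reach the same state, which is expanded once, and the
number of distinct dendrograms equals the number of distinct terminal
states visited.  Counting is by graph traversal (a visited set), not by
summing branch counts — different intermediate states can complete to
overlapping tree sets, so path-count recurrences would overcount.  Keys are
128-bit blake2b digests (collision probability negligible at 10^7 states).
A `max_trees` cap (default 10^7) turns the count into a lower bound with
`truncated=True`.  The validation oracle is a no-memoization recursion over
all choices (guarded to n ≤ 8), deduplicating final trees only.

## Survey statistics

Prevalence is n_tied/n_analyzed with a binomial CI; the default is the Wald
interval `p̂ ± z·√(p̂(1−p̂)/n)` clipped to [0,1], with Wilson and
Clopper–Pearson as options (statsmodels implementations).  Wald is the
default because it reproduces the integer-rounded percentages quoted in the
motivating survey (46%, 36–56% for 47/102); Wilson gives 37% at the lower
bound.  Extrapolations are `round(fraction × N)`: for N = 2239 this gives
1032 (CI 815–1248); the survey literature quotes 816 at the lower bound,
one more than round(0.36405 × 2239) = 815.1 — the package reports its own
computed value and documents the 1-article discrepancy rather than
hard-coding the printed one.  Dendrogram counts of tied sources are binned
into [2–10], [11–100], [101–1000], [1001–10000], [>10000]; only the outer
three bins are quoted in the motivating survey, and the middle decades are
the natural completion of the log-decade partition.  Truncated counts
(≥ the 10^7 cap) land in the open top bin.

## Synthetic data

`random_grid_matrix` draws distances uniformly from a lattice {k·grid_step}
— the resolution mechanism itself, not post-hoc duplication — so tie
probability is controlled by grid coarseness.  `random_genotype_table`
defaults (10 individuals × 30 loci, 4 alleles per locus, ploidy 2) mirror a
typical microsatellite study scale, where shared-allele similarities
collide at 4 decimals.  `planted_tie_matrix` composes blocks with known
counts — an equilateral block of k items (all pairwise 1) admits
(2k−3)!! trees, a 3-chain (1, 1, 2) admits 2, a singleton 1 — and the total
count is the product.  Inter-block distances form the tie-free ultrametric
ladder `separation·(1 + max(block_i, block_j))`; a *constant* separation
would itself create an equilateral tie among block roots and break the
product formula, so independence of blocks requires the ladder.  All
generators take explicit seeds and are bit-reproducible; no global seed is
used.

What a green synthetic test does not establish: the generators produce
exact decimal matrices with clean block structure; real published matrices
carry transcription noise, asymmetric rounding and missing entries, and
their tie structure can interact across the whole matrix rather than in
separable blocks.  The two published case matrices (a 10-taxon grasspea
study with a mid-tree tie and band [1.0459, 1.1112]; a 22-genotype chilli
study with 2,655,193 binary dendrograms) are not redistributable here;
`fixture_nested_tie` is a synthetic stand-in reproducing the *structure* of
the first case (it uses the two published band endpoints as input
distances, and the machinery recovers 2 trees and that exact band), not a
transcription of its data.

## Numerical choices and edge cases

- Rounding: half-away-from-zero; half-even is deliberately not used.
- Matrix symmetry is required exactly at construction; readers symmetrize
  only after verifying agreement within half a printed unit.
- Newick export: `raw_heights` (branch = parent height − child height) or
  `ultrametric_halved` (all lengths /2, one extra decimal digit so halves
  stay exact); labels with metacharacters are quoted.
- The minimal tied fixture (1, 1, 2) is stated at p = 1 so the A–C mean of
  1.5 is exact at the working precision under re-rounding.
- `upgma` on a similarity matrix is an error; callers convert explicitly.

## Limitations

- Only average linkage (UPGMA) is implemented; ties affect complete or
  Ward linkage too, but their variable-group analogues differ.
- Enumeration memory grows with the number of distinct states; instances
  beyond ~10^7 trees report lower bounds.
- No graphical rendering of dendrograms or bands; structures are exported
  as newick/JSON for external plotting.
- No population-genetic realism in the genotype generator (no mutation
  model, no Hardy–Weinberg structure); it emulates allele-count scale only.
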