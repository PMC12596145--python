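# Methods

This note documents the models, defaults and numerical choices behind
`phylogeoscan`, and what its synthetic tests do and do not establish.

## Problem setting

The package scans an alignment of homologous nucleotide sequences, one per
geolocated sample, for genomic windows whose local phylogeny is unusually
concordant with environmental structure. The underlying idea is standard in
phylogeography: if a region of the genome contributes to (or hitchhikes with)
adaptation along an environmental gradient, the trees inferred from that region
will group samples by environment more strongly than the genomic background
does. The analysis is descriptive and correlational — a low tree distance or a
significant Mantel/PROTEST result flags a window for inspection; it is not a
selection test.

## Sequence alignment

Pairwise alignment is classical dynamic programming (Needleman–Wunsch for
global, Smith–Waterman for local) with affine gaps, delegated to Biopython's
`PairwiseAligner`. Defaults: match +1, mismatch −1, gap open −2, gap extend
−0.5, where a gap of length L costs `open + (L−1)·extend`. Among co-optimal
alignments the first traceback reported by the aligner is used; this is
deterministic for fixed inputs. The ambiguity code `N` scores as a mismatch
against every character including another `N` — conservative, so unknown bases
never inflate similarity.

The multiple alignment is a reference-guided **star alignment**: every sequence
is aligned globally to a reference (default: the longest input, ties broken by
input order), and any gap a pairwise alignment inserts into the reference is
propagated to all rows ("once a gap, always a gap"). This is simple,
deterministic and adequate for the moderately diverged, mostly co-linear
sequences the pipeline targets; it is *not* equivalent to progressive MSA and
will underperform on sequences with large rearrangements or very different
lengths. Pre-aligned input can (and for serious use should) be supplied
directly; `align: auto` runs the aligner only when input lengths differ.

## Windows and filters

Coordinates are 0-based, half-open `[start, end)` everywhere, including the
output table. Windows start at 0, step, 2·step, …; a trailing partial window is
kept by default when it has ≥ 2 columns (discarding the alignment tail silently
would lose signal). A window size exceeding the alignment length degrades to a
single full-length window with a warning.

The gap filter removes columns whose gap fraction exceeds `max_gap_fraction`
(default 0.5); both `-` and `N` count as gaps by default because the filter's
purpose is excluding low-quality regions. The filter is applied per window,
after windowing — the bounds a window reports never change, only its retained
columns. The variability filter drops windows whose mean pairwise
dissimilarity under a chosen string metric falls below a threshold (default 0,
i.e. off). Similarities (Jaccard, Jaro, Jaro–Winkler, Dice, normalized
Smith–Waterman) are converted to dissimilarity `1 − s`; edit distances are used
raw. Gap characters inside a window are treated as ordinary characters by the
string metrics: they are used for variability *ranking*, not inference, and
indel divergence is divergence. Jaccard uses k-mers with k = 3 by default.
Damerau–Levenshtein is the optimal-string-alignment (restricted) variant; the
unrestricted variant would be a straightforward extension.

## Genetic tree inference

The internal engine is **p-distance + neighbor-joining**: entry (i,j) is the
proportion of mismatching sites among columns where neither sequence has a gap
or `N` (pairwise deletion); a pair with no comparable site gets the configured
maximum (default 1.0) with a warning. NJ follows Saitou–Nei with two
reproducibility rules: the Q-matrix minimum is tie-broken toward the smallest
(i,j) index pair, and a negative branch length is clamped to zero with the
deficit transferred to its sister edge (preserving the pair's summed length).
NJ is exact on additive matrices, which the test suite exploits directly.
Model-corrected distances (JC69 and relatives) and likelihood engines are out
of scope; any external FASTA→Newick program can be plugged in through
`tree_engine: "external:<executable> [args]"`.

Bootstrap: columns are resampled i.i.d. with replacement (same column count),
100 replicates by default, each replicate's seed derived deterministically from
the window seed. The majority-rule consensus keeps exactly the bipartitions
whose replicate frequency is **strictly greater** than the threshold (default
0.5) — a split in exactly half of the replicates is excluded. Thresholds ≥ 0.5
guarantee the retained splits are pairwise compatible, so the consensus is
well defined. Retained edges carry their frequency as support and the mean
branch length over the replicates containing them; pendant edges carry the
mean over all replicates (the averaging choice is a documented convention —
consensus branch lengths have no canonical definition). An optional
`min_clade_support` collapses weakly supported consensus edges to polytomies
rather than dropping whole windows; collapsing keeps the remaining signal
usable downstream.

## Climate trees

Variables whose **sample variance (n−1 denominator)** is not strictly above
`variance_threshold` (default 0, so constant columns always drop) are removed.
Each retained variable yields the |xᵢ − xⱼ| distance matrix and an NJ tree; a
combined tree over all retained variables uses the full Euclidean distance.
Variables are not standardized by default; a `standardize` flag z-scores them
first, which matters whenever units differ. Geographic coordinates supplied as
columns are treated as ordinary variables — the package measures distance in
climate-variable space attached to geolocated samples, not great-circle
distance.

## Concordance statistics

* **Robinson–Foulds**: |B₁ Δ B₂| over nontrivial bipartitions, each
  canonicalized as the side not containing the lexicographically smallest
  leaf; the normalized variant divides by |B₁| + |B₂| (defined as 0 for two
  stars). Polytomies simply contribute fewer bipartitions.
* **Least-squares distance**: √Σᵢ<ⱼ (d₁(i,j) − d₂(i,j))² over patristic
  matrices, pair order fixed by sorted leaf labels.
* **Euclidean tree distance**: identical to the least-squares distance under
  the default patristic vectorization; a clade-indicator vectorization
  (distance √RF) is available because "vector representation of a tree" is
  genuinely ambiguous and both readings are useful.
* **Mantel test**: correlation (Pearson default, Spearman with average ranks
  optional) between condensed upper triangles; the null simultaneously
  permutes rows and columns of the second matrix by a random taxon
  permutation. The genetic input is the **mean patristic matrix over the
  bootstrap replicate trees** — averaging integrates out replicate noise and
  avoids the many-zeros pathology of consensus stars; the climatic input is
  the per-variable Euclidean distance matrix.
* **PCoA**: classical scaling (double-center −½D², eigendecompose, scale
  eigenvectors by √λ). Negative eigenvalues (non-Euclidean input, routine for
  tree distances) are dropped with a warning; if fewer than k positive axes
  exist, fewer are returned — a 1-D climate variable legitimately ordinates
  onto a single axis.
* **PROTEST**: Procrustes m² between the two ordinations after centering and
  scaling to unit sum of squares, optimal rotation from the SVD of X'Y
  (reflections allowed by default; a rotations-only flag exists). Statistic
  √(1 − m²); the null permutes the rows of the second configuration. k
  defaults to min(3, n−1).

All permutation p-values use the add-one rule `(1 + #{r* ≥ obs}) / (1 + P)`
with P = 999 by default, one-sided upper tail (two-sided available for
Mantel); p = 0 is never reported. An `all_permutations` mode enumerates every
taxon permutation and returns the exact p `#{r* ≥ obs} / n!`. The observed
statistic is deliberately computed through the identical code path as the
permuted ones so the identity permutation ties it bit-for-bit — otherwise
BLAS memory-layout effects can shift exact p-values by one permutation. No
multiple-testing correction across windows or variables is applied; rows are
not independent (windows overlap taxa and, with step < size, columns), so any
correction is left to the analyst.

## Determinism and parallelism

Every window's random streams derive from `sha256(rng_seed, window_start)`
(and, below that, the variable name and test name), truncated below 2³¹.
Consequences: results are byte-identical across runs, across worker counts,
and a window's results do not change when other windows are added or removed.
Worker processes only compute; all artifact writing happens in the parent, in
deterministic order. The resolved configuration and package version are
written alongside every run.

## Synthetic data: what it emulates, what it does not

The generator plants the exact signal the pipeline is built to detect: taxa
assigned to groups round-robin; a random ancestral sequence; a hotspot
interval where each group carries its own substitution pattern (per-site
probability `hotspot_divergence`, default 0.3); i.i.d. background substitutions
elsewhere (default 0.01); one climate variable separating group means by
`climate_effect` standard deviations (default 3) with unit noise, plus
independent standard-normal noise variables (default 3). Defaults are 12 taxa,
2 groups, 500 bp, hotspot [200, 300) — sized so the hotspot exactly fills one
default 100-column window. Group evolution is star-phylogeny-per-group: no
coalescent genealogy, no indels, no rate heterogeneity, no linkage decay, no
spatial autocorrelation among climate variables. A green planted-truth test
therefore establishes that the pipeline recovers a clean block-structured
association; it says nothing about power under realistic demography or about
robustness to alignment error.

The companion generator for tree tests builds random binary topologies with
uniform branch lengths in [0.05, 1] and returns their patristic matrices,
which are additive by construction — the sharpest possible oracle for NJ.

## Numerical choices and edge cases

* Q-matrix ties → smallest index pair; negative NJ lengths → clamp with
  transfer; negative intermediate distances → clamp to 0.
* Degenerate Mantel input (constant distance vector, e.g. a window with no
  variable sites) → flagged result with NaN statistic and p, never a crash;
  degenerate PROTEST ordinations likewise yield NaN in the results table.
* Newick output: branch lengths at 6 significant digits, support as internal
  node labels; parse failures report a character offset located by a
  structural scan.
* Results CSV: floats at 6 significant digits, rows sorted by
  (window_start, climatic_variable).
* Scale: exhaustive oracle checks in the test suite run the 2-letter alphabet
  exhaustively to length 5 and sample 4-letter pairs to length 6 — the full
  4-letter cross product is astronomically larger with no additional
  discriminating power.

## Known limitations

Star MSA (see above); p-distance saturates for deep divergence; NJ is a
point estimate per replicate with no model of rate variation; Mantel tests
have known elevated type-I error under spatial autocorrelation of both
matrices (not simulated here); the climate tree for a single variable is a
tree built from 1-D distances, i.e. mostly a visualization device — the
matrix-level tests carry the inferential weight.
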