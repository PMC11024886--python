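# Methods

## Scope and model

`specnet` organises MS/MS feature spectra by pairwise spectral
similarity and exposes the structures analysts actually inspect: a
global 2D overview, cluster subdivisions, and local network/heatmap
views. The package deliberately stops at data tables — rendering,
interactivity and dashboards are out of scope, as are learned similarity
models (their score matrices are consumed as CSV input), library search,
and upstream feature detection.

## Preprocessing

Each spectrum is reduced to a normalised peak list: peaks within a merge
tolerance are combined (intensity-summed, intensity-weighted mean m/z,
iterated to a fixpoint so no two surviving peaks remain within
tolerance), intensities are scaled to a base peak of 1.0, and peaks
below a relative-intensity floor are dropped. Spectra left with too few
peaks are discarded with a warning. Defaults — merge tolerance 0.01 Th,
floor 0.001, minimum 2 peaks — are conservative values in line with
common matchms-style pipelines; all are configurable. The ordering
(merge, then normalise, then floor) makes the operation idempotent,
which the tests assert.

## Modified cosine

Candidate fragment pairs match directly within a fragment tolerance
(default 0.1 Th, configurable; a widely used value rather than a derived
one) or shifted by the precursor mass difference. Matching is greedy
one-to-one by descending intensity product — the convention of the
molecular-networking lineage — with deterministic tie-breaking (direct
match preferred over shifted, then lowest peak indices). The greedy
score is bounded above by the optimal-assignment score; the test suite
quantifies this gap with a Hungarian-algorithm oracle and cross-checks
the implementation against matchms to 1e-9 on planted-family fixtures.
Optional m/z and intensity weighting exponents default to 0 and 1 (raw
normalised intensities). No minimum matched-peak count is imposed by
default, since minimum-overlap requirements make connectivity overly
stringent; an optional `min_matches` zeroes sparse overlaps.

## Embedding

t-SNE runs on d = 1 − s, the simplest monotone transform of similarity
to distance (sqrt or angular variants were considered and rejected as
needless complexity at these scales). Initialisation is the first two
principal coordinates of the distance matrix, scaled to std 1e-4: a
deterministic anchor that makes layouts reproducible across reruns and
seeds meaningful. Perplexities ≥ (n − 1)/3 are infeasible for the
underlying optimiser and are skipped with a warning. Each grid point is
scored by Pearson and Spearman correlation between condensed
high-dimensional and 2D distances; the default selection rule takes the
maximal Pearson correlation with ties to the lowest perplexity — a
pragmatic default for an intrinsically user-judged choice.

A note on equivariance: the deterministic PCoA initialisation is exactly
permutation-equivariant (tested to 1e-12), but the full t-SNE optimiser
is not — permuting the input reorders floating-point summations, and the
optimisation amplifies those last-bit differences into visibly different
(though structurally equivalent) layouts. Reproducibility is therefore
guaranteed for a fixed input ordering and seed, not across orderings.

## k-medoid clustering

Classical PAM: greedy BUILD (start at the most central point, add the
point with the largest objective decrease) followed by best-improvement
SWAP until no swap lowers the sum of within-cluster distances to
medoids. All ties break toward the lowest index and there are no random
restarts, so runs are exactly reproducible; the `seed` argument exists
only for interface symmetry. The objective is asserted non-increasing
across SWAP steps. On well-separated planted blocks PAM attains the
exhaustively verified optimum and recovers the planted partition (ARI
1.0); on unstructured random matrices best-improvement SWAP can stop in
a local optimum, which is inherent to PAM and documented rather than
patched with restarts. The default k grid {4, 8, 12, 16, 20} (capped
below n) spans coarse overview groupings to small localized clusters.
Hierarchical medoid-linkage alternatives are deliberately not
implemented; automatic k selection is out of scope.

## Networks and views

Thresholding is inclusive (score ≥ threshold) everywhere, and the augmap
adjacency masks reuse the same rule, so the two are bit-consistent — a
cross-module test asserts mask equality with `build_network` on the same
submatrices. The top-K filter is mutual by default (an edge must rank in
both endpoints' K heaviest neighbors, ties to the lower partner index),
matching the molecular-networking convention; a single-sided mode is a
flag. Ego networks use induced-subgraph semantics: all edges among the
nodes within the hop radius, not only the BFS tree, preserving true
local topology.

Fragmap bins fragments at floor(mz / bin_width) with bin width 0.01 Th
by default; neutral losses (precursor − fragment, kept when ≥ 10 Th to
avoid near-precursor artifacts) share the same factorized axis and are
flagged per cell. Occupied bins are factorized to consecutive indices in
ascending m/z order; beyond `max_bins` (default 200) the bins with the
highest total intensity across the selection are kept. The
representative m/z of a bin is the intensity-weighted mean of its
members. An optional `min_occurrence` filter (default 1, i.e. off) can
require a bin to appear in several spectra.

## Synthetic libraries

The generator plants molecular families: each family has a random
fragment backbone, a shared core (fraction `shared_fraction`, default
0.7) inherited exactly by every member, per-member analog shifts
(uniform in ±20 Th, applied to the precursor and the non-shared backbone
peaks — exercising the shifted matching), and noise peaks with m/z
uniform in [50, precursor] and log-uniform intensities in [0.01, 1].
Member 0 of each family is the unshifted prototype. The default study
fixture is 5 families × 10 members (50 spectra), sized for desk-scale
analysis of every stage within seconds.

What the generator does **not** emulate: realistic fragmentation
chemistry, isotope patterns, adducts, charge states, or
instrument-dependent noise structure. Passing tests therefore
demonstrate the correctness of the algorithms and plumbing on data with
planted ground truth — not annotation performance on real biological
data, where family structure is far less clean.

## Determinism and numerics

All randomness flows from explicit integer seeds (numpy `default_rng`
keyed on (seed, family seed, index) tuples for the generator; the t-SNE
`random_state` for the embedding). A session rerun with an identical
configuration is byte-identical, verified by hashing every artifact.
Score matrices are validated on construction (symmetry to 1e-9, unit
diagonal, [0, 1] range); externally loaded matrices tolerate asymmetry
only up to 1e-6 (then symmetrised by averaging) and are clipped/diagonal
-corrected with warnings. MGF output prints six decimals, so a first
round trip is exact to 1e-6 and subsequent round trips are bitwise
stable.
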