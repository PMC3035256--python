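# Methods

## Gene families from alignment hits

Families are built from all-vs-all protein alignment results in 12-column
BLAST tabular format. A hit is *significant* when its E-value is at or
below the cutoff (default 10⁻⁵; more liberal cutoffs mostly add poor
alignments without changing families). Two distinct sequences are
directly linked when **both** directions qualify: a hit with query *a*,
subject *b* whose aligned length covers at least `min_coverage` (default
0.5) of *a*'s full length at `pct_identity/100 ≥ min_identity` (default
0.5), and likewise with *b* as query against *b*'s length. Choices worth
stating explicitly:

* **Coverage denominator** is always the *query's* full sequence length
  for that direction, never the subject's and never the alignment span.
* **Identity** is the hit's own percent-identity field, i.e. measured
  over the aligned region, as alignment tools report it.
* **Multiple HSPs** for a direction are not tiled or merged; the
  direction qualifies if any single hit qualifies. Tiling would only
  loosen the rule and needs arbitrary overlap conventions.
* **Self-hits** are parsed but never form pairs.
* **Transitive closure.** The rule is pairwise, but families must
  partition the catalog, so families are the connected components of the
  pair graph (single linkage). Every cataloged sequence is a node, so
  unmatched sequences become singleton families.
* **Determinism.** Family ids are `F` + zero-padded index, assigned in
  order of each component's lexicographically smallest member, so
  identical inputs give identical outputs regardless of hit order.

## Pan-matrix, occupancy, weights

The pan-matrix is strictly binary: a family with several members in one
genome (paralogs) still contributes a single 1. Occupancy kⱼ ∈ {1..G} is
the number of genomes carrying family j; the occupancy spectrum counts
families at each occupancy. Weight schemes are pure functions of
occupancy, which guarantees the invariant that equal-occupancy families
get equal weights:

| scheme        | wⱼ               | emphasis                    |
|---------------|------------------|-----------------------------|
| `uniform`     | 1                | none (default)              |
| `drop_orfans` | 0 if kⱼ=1 else 1 | robustness to gene-finder noise |
| `shell`       | (kⱼ−1)/(G−1)     | widely conserved families   |
| `cloud`       | (G−kⱼ)/(G−1)     | rare / strain-specific families |

The shell and cloud ramps are the simplest monotone forms; any
alternative (sigmoidal, stepwise) can be added behind the same scheme
interface. The `drop_orfans` / `drop_core` boolean flags zero the
corresponding columns *after* the base scheme, so discarding ORFans
composes with shell or cloud emphasis. Core columns are kept by default:
they contribute |1−1| = 0 to every pairwise difference and are therefore
harmless in the numerator, though they do enlarge W. A configuration
whose weights all vanish (e.g. `cloud` on a pure-core matrix) is an
error, not a silent degenerate tree.

## Distances

The weighted relative Manhattan distance D(i,k) = (1/W) Σⱼ wⱼ|Mᵢⱼ−Mₖⱼ| is
computed for all pairs at once via the binary identity
|x−y| = x + y − 2xy, i.e. one weighted Gram product instead of a per-pair
loop; results are clipped to [0, 1] and symmetrized to remove float
round-off (≤1e-15). The test suite checks this vectorized path against an
explicit per-pair, per-column loop on 1,000 random matrices.

Interpretation: D is the proportion of the pan-genome's weight on which
two genomes disagree. Families absent from *both* genomes of a pair count
as agreement — adding such families (present elsewhere in the pan-genome)
lowers the pair's distance. The Jaccard distance 1 − a/(a+b+c), provided
unweighted for comparison, ignores those columns entirely, which is the
substantive argument for preferring the relative Manhattan form inside a
pan-genome. (Jaccard is implemented in its standard form; a pair of
genomes sharing no present family at all has an undefined Jaccard
distance and raises.)

## UPGMA and bootstrap

UPGMA merges the pair of clusters with the smallest average linkage;
the new cluster's distance to the rest is the size-weighted mean, which
is exactly the unweighted mean over all original leaf pairs. Node height
is merge distance / 2; average linkage is reducible, so heights are
monotone and the tree ultrametric. Two numerical choices:

* **Tie-breaking.** Clusters are labelled by their smallest genome id;
  among pairs within 1e-12 of the minimal distance, the lexicographically
  smallest (label, label) tuple merges first. The 1e-12 tolerance makes
  the recursive update and a direct mean over leaf pairs (which differ by
  ~1e-16 rounding) take identical decisions; distances that are genuinely
  different on binary data differ by far more than the tolerance.
* **Bootstrap.** Classic column bootstrap: each replicate draws exactly n
  column indices with replacement; each drawn column keeps its weight and
  W is recomputed per replicate, which is the only composition consistent
  with weighted distances. (The alternative — recomputing scheme weights
  from the resampled occupancies — is noted but not the default.)
  A reference node is supported by a replicate iff the replicate tree has
  an internal node with the *same two child leaf sets* — stricter than
  clade matching. Replicate r is a deterministic function of (seed, r)
  via independent child seed sequences, so supports are reproducible and
  invariant to running replicates in any order; a replicate whose
  resampled W is zero is redrawn, failing after 100 attempts (only
  reachable when nearly all weight sits on a few columns).

Newick output writes branch lengths as height differences and supports as
integer internal-node labels; labels with reserved characters are quoted.

## Synthetic data

* **Planted spectra** (`simulate_panmatrix`): core families fill all G
  genomes; shell and cloud families draw an occupancy uniformly from
  their configured ranges and then a uniformly random genome subset of
  that size. Defaults put shell occupancy in the upper majority below G
  and cloud in the lower minority, so the planted class counts are
  exactly recoverable from the spectrum.
* **Gain/loss evolution** (`simulate_gainloss`): along each branch of
  length t of a given guide tree, each present family survives with
  probability exp(−loss·t) independently, and Poisson(gain·t) novel
  families arise. This is the simplest independent-events model; it
  exists to produce pan-matrices whose true tree is known. It does not
  model correlated gain/loss, horizontal transfer of blocks, rate
  heterogeneity across families, or sequence evolution — so passing
  recovery tests demonstrates correctness of the pipeline's inference
  machinery, not robustness to those real-data phenomena.
* **Mock alignment tables** (`simulate_alignment_table`): qualifying
  reciprocal hits (75% coverage, 60–95% identity, E ≤ 10⁻²⁰) for every
  within-family pair plus self-hits, and decoy cross-family hits cycling
  through the three failure modes — coverage below 50% at high identity,
  identity below 50% at high coverage, and a fully qualifying but
  one-directional hit — so each clause of the reciprocal rule is
  exercised independently.

## Problem sizes and frozen bounds

Randomized checks use matrices up to G = 10 genomes × 200 families
(1,000 draws for the distance identity), 100 random UPGMA-vs-reference
trials at G ≤ 8, and 50-seed gain/loss studies on balanced 4- and 8-leaf
guide trees (root genomes of 120–150 families, gain 3.0 and loss
0.15–0.3 per unit branch, bootstrap B = 30–50). At these low-noise
settings a pre-build oracle run recovered the true topology in ≥ 49/50
seeds; the regression bound asserts ≥ 45/50 (90%). Mean true-clade
bootstrap support was monotone in clade separation over the grid
s ∈ {0.1, 0.5, 2.0} (≈ 80 → 100%).

## Known limitations

* Families come from a simple cutoff rule on pairwise alignments; single
  linkage can chain distinct families through intermediate sequences, and
  all-vs-all alignment scales quadratically in genome count.
* The distance is a functional, not an evolutionary, dissimilarity; the
  UPGMA tree assumes rate homogeneity (ultrametricity) and should not be
  read as a dated phylogeny.
* Bootstrap node matching is strict (both child leaf sets), so supports
  are conservative relative to clade-based matching.
* Jaccard bootstrap supports are not offered; the resampling scheme is
  defined for the weighted Manhattan pipeline.
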