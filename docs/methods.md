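# Methods

## Model and assumptions

The method makes only the two assumptions common to DE analysis — most genes
are stable, and DE genes are globally unbiased (some up, some down) — and
otherwise avoids a parametric count model. A sample is the observed count
vector `c = (c_g)`, total `M`. The observed library is treated as one
realisation of a multinomial read-sampling process with gene probabilities
`p_g = c_g / M`; all downstream distributions are estimated by re-simulating
that process. Genes with `c_g = 0` have `p_g = 0` exactly: a gene that drew
no reads can never receive a resampled read, and is pinned to the lowest
expression bin.

Expression is summarised per gene by a character function onto `P` ordered
bins, constrained so that within any realisation (a) more assigned reads
never means a lower bin and (b) equal assigned reads means equal bins.
Because the map depends on all genes jointly and is scale-invariant, no
closed form is attempted; the per-gene bin distribution is the empirical
histogram over `I` independent resampling iterations.

## Segmentation

Within an iteration, the expressed genes are ordered by decreasing assigned
count and the cumulative-sum curve is split into `P − 1` contiguous
segments, each fitted by its own unconstrained least-squares line
(continuity across segments is deliberately not enforced), minimising total
squared residual. The exact optimum is found by dynamic programming with
per-segment costs from prefix sums (`O(P·n²)` time, `O(n²)` memory).
Numerical choices:

* The curve is first detrended by its global least-squares line — per-segment
  SSE is invariant under subtracting any global linear function of position,
  and working on residuals avoids catastrophic cancellation in the prefix-sum
  cost formula when cumulative counts are large.
* Among equal-error segmentations (relative tolerance `1e-9`) the
  lexicographically smallest breakpoint vector is chosen, via a greedy
  left-to-right reconstruction against the suffix DP table. This makes the
  optimiser deterministic and directly comparable to exhaustive enumeration.
* Ordering ties (equal assigned counts) are broken by gene id so iterations
  are reproducible; after segmentation, any run of equal-count genes
  straddling a boundary is reassigned the run's majority bin (higher bin on
  a tie), restoring the equal-value ⇒ equal-bin constraint.
* If fewer expressed genes than segments exist, the top genes take one
  segment each (bins `P, P−1, …`) and a warning is logged.
* When the number of expressed genes exceeds `subsample_threshold` (default
  2,000), breakpoints are located on every `subsample_step`-th gene (default
  10) and mapped back to all genes through the count value at each
  breakpoint, keeping equal counts in equal bins by construction. The
  threshold is the package's own speed/accuracy trade-off: the quadratic DP
  dominates runtime, and at several thousand genes the subsampled breakpoints
  are visually indistinguishable from the exact ones on cumulative curves.

Random streams are derived per `(seed, sample index, iteration)`, so samples
and iterations can be computed in any order (or in parallel) with identical
results, and any rerun is bit-identical.

## DE calling

Histograms are compared by the maximum-norm distance between cumulative
distributions; ranking is by decreasing distance, then decreasing mode
distance (modes resolve ties to the smallest bin), then gene id. The DE call
requires `dis ≥ δ − ε` (ε = 1e-9 absorbs float accumulation over `I`
frequency increments; with δ = 1.0 and I = 100 an exact 1.0 is common) and
mode distance ≥ the mode threshold. Direction is up when the mode in the
second (stress) sample exceeds the mode in the first (control). With `K`
replicates, per-replicate histograms are averaged before comparison; the raw
per-iteration bins of all replicates are concatenated for dispersion and
stable-gene use. The default thresholds (δ = 1.0, mode distance ≥ 5 at
P = 15) are kept as independent parameters — the mode threshold is *not*
rescaled automatically when P changes.

Robust DE sets intersect the per-member up- (or down-) regulated sets within
a group of conditions sharing a response or time class; a group needs at
least two members for the intersection to mean anything.

## Dispersion diagnostics

`ψ_p(q)` is estimated as the frequency of (gene, ordered iteration pair)
events mapping bin `p` in one sample to bin `q` in the other — the
probability is taken jointly over genes and iteration pairs. In
self-comparison the matched pairs `i = i′` are excluded, since including a
sample's iteration against itself would inflate neutrality by exactly the
diagonal; the flag is recorded on the output. `Ñ_p` is exposed as the
recommended diagnostic for choosing `P`; no automatic P selection is done.

## Stable genes

The procedure is a reconstruction by design from two constraints: stability
is a longest-increasing-subsequence property of rank orders, and one stable
set is produced per iteration and intersected. Concretely, iteration `i` of
sample a is paired with iteration `i` of sample b (matched pairs keep the
cost linear in `I`); genes with ≥ 1 assigned read on both sides are the
*active* universe; ordering is by assigned-count rank (gene-id tie-break).
The LIS backtrace is deterministic (patience sorting; each element records
the current top of the previous pile). Since the LIS is generally not
unique, `lis_union` optionally reports every gene lying on *some* optimal
chain. An alternative design — running the LIS on bins rather than
assigned-count ranks — would coarsen the order and admit more genes; ranks
were chosen because the bin histograms already serve the DE side, and ranks
make "stable" a strictly stronger statement.

Stable and called-DE sets are not forced to partition the gene universe —
both involve confidence thresholds — but they are disjoint on every tested
dataset, and the suite asserts this.

## Synthetic data

The count generator draws baseline means log-normal (`meanlog 1.5`,
`sdlog 1.5` on the natural log — a heavy-tailed abundance profile spanning
roughly four orders of magnitude, as bulk RNA-seq does) and deliberately
*not* negative binomial, so benchmarks are not biased toward the model
parametric DE callers assume. Planted genes alternate up/down at the given
fold, keeping the global signal unbiased; per-sample counts are one
multinomial draw of the library size with probabilities proportional to the
condition means, so genes compete for reads and library size is exact. What
it does not emulate: biological replicate overdispersion beyond resampling
noise, gene-length effects (inputs are counts, length is absorbed upstream),
and correlated expression modules — so passing recovery tests shows the
inference machinery works under its own sampling model, not that real
tissue data will be as clean.

The allele generator evolves one reference base per locus along a supplied
ultrametric tree: per branch and locus, substitution events are
Poisson(rate × length) and at least one event switches the base uniformly to
another (multiple hits within one branch collapse to one switch — adequate
at the low per-branch rates targeted). Coverage is uniform in a range, so
the coverage filter can be exercised.

## Evaluation harness

Truth labels come from measured log fold changes: DE above 1.5, non-DE below
1.0, the band between unassigned and excluded from every metric (panels skip
unassigned genes without consuming rank positions). AUC is the Mann–Whitney
probability that a random DE gene outranks a random non-DE gene. In the
threshold sweep the non-DE cutoff is scaled proportionally with the DE
cutoff (ratio 1.0/1.5 by default, exposed as a knob) since the appropriate
coupling is a judgement call.

## Phylogenies

Hamming distances are normalised per pairwise-complete locus count, making
trees comparable across locus subsets of different sizes; a pair with no
co-called loci is an error, not a silent zero. UPGMA is implemented directly
(≈60 lines) rather than delegated to scipy because a deterministic tie rule
is required: equal-distance merges take the lexicographically smallest pair
of clusters (compared by sorted leaf names). scipy's average linkage is used
as an independent cross-check in the tests. The locus coverage rule defaults
to *every* non-missing sample reaching the cutoff, with an `--any-sample`
relaxation, since either reading of "at least 100 reads covering the SNP" is
defensible.

## Problem sizes and defaults

The shipped defaults are the package's reference conditions: `P = 15`,
`I = 100`, `R = auto`, δ = 1.0, mode threshold 5 (the `phalaris` profile);
`P = 20, R = 10^7` (the `maqc` profile). The acceptance script and the
recovery tests run 5,000 genes with 50 planted 8-fold changes at library
10^6 and the full `I = 100`, chosen as the smallest scale at which the
stable-set intersection and the mode-distance threshold behave as they do on
full-size libraries; phylogeny recovery uses 2,000 loci on a 5-taxon tree at
rate 0.05 per unit branch length (expected per-branch divergence of 5–10%,
comfortably above the sampling noise of 2,000 loci, i.e. a "moderate rate").

## Known limitations

* The quadratic-cost segmentation is exact only up to the subsampling rule;
  callers needing the exact optimum above the threshold can raise
  `subsample_threshold` at quadratic cost.
* Zero-count genes are kept (they pin to bin 1) rather than dropped;
  datasets where most genes are zero inflate bin 1 and the ψ row for p = 1.
* `R` should not greatly exceed the real mapped-read total when the count
  table has been heavily downsampled: resampling cannot reintroduce
  information the counts no longer carry.
* The stable-gene definition is strict (rank preserved in *every*
  iteration); stable sets are small by design and shrink as `I` grows.
* Allele matrices are consumed as pre-called symbols; consensus calling,
  VCF ingestion and read-level simulation are out of scope.
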