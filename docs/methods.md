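# Methods

This note records the models gcfkit implements, the defaults it ships, the
numerical choices behind them, and what the synthetic benchmarks do and do
not establish.

## Domain-architecture distance

A BGC is an ordered list of protein-domain copies, each copy optionally
carrying a residue sequence. Two BGCs of the same metabolite class are
compared with three components, each in [0, 1]:

- **Jaccard index** `J` over the sets of domain types — shared content.
- **Adjacency index** `A` — Jaccard over the sets of unordered adjacent
  domain-type pairs, a cheap proxy for synteny of the architecture. Lists
  with fewer than two domains contribute no pairs: against a list that has
  pairs the index is 0; two single-domain lists score 1 when the types match.
  A tandem repeat pair (x, x) is kept distinct from absence.
- **Domain sequence similarity** `DSS` — for every shared domain type, copies
  are matched one-to-one by an exact maximum-weight assignment
  (`scipy.optimize.linear_sum_assignment`) on pairwise copy similarities
  (1 − normalised edit distance, computed with edlib; 1.0 when neither copy
  has a sequence). Excess copies of shared types and every copy of a type
  present in only one BGC count as unmatched with similarity 0:
  `DSS = Σ matched / (n_matched + n_unmatched)`.

The distance is `1 − (w_J·J + w_A·A + w_D·DSS)` with default weights
(0.2, 0.05, 0.75). The weights put most mass on copy-level similarity, with
content next and order least; they are plain configuration
(`SimilarityWeights`), not fitted quantities. Copy matching uses the exact
assignment rather than a greedy heuristic: the assignment is deterministic,
costs nothing at these matrix sizes (copies per type are almost always ≤ 3),
and provably equals the brute-force optimum the test suite checks against —
a greedy matcher can be off on 3×3 instances. Cross-class pairs are never
formed; each class is analysed independently.

## Family assignment and the cutoff sweep

Families at cutoff `c` are connected components of the graph with edges
where `d ≤ c` (union-find with union by size and path compression; verified
against a BFS oracle). Family ids are `<class>_<k>`, numbered by smallest
member id, so labels are stable across runs. A singleton is a component of
size one.

Distances are computed once; the sweep sorts edges by distance and replays
unions incrementally, snapshotting metrics at each grid point (default grid
0.1–0.9, step 0.1). Because threshold graphs are nested, the partition at a
smaller cutoff refines the partition at a larger one; family counts and
singleton counts are non-increasing and mean family size non-decreasing in
the cutoff. These invariants are property-tested on simulated inventories.

Cutoff selection offers two policies. `fixed(c)` returns `c` (warning if
off-grid). `knee` min-max normalises both axes of the mean-family-size curve
and returns the grid point with maximum perpendicular distance to the chord
joining the curve's endpoints — the last cutoff before mean family size
explodes, which is where merging starts absorbing dissimilar clusters. Ties
break to the smaller (more conservative) cutoff, so a perfectly linear curve
yields the grid start. Axis normalisation makes the choice scale-free in the
size units.

## Heavy-tail models of family sizes

Three discrete models on integer support `k ≥ xmin`:

- power law `p(k) = k^−α / ζ(α, xmin)` (Hurwitz zeta);
- lognormal: the continuous density evaluated at integers, renormalised by
  summation to a truncation bound `max(10·max(k), 10⁶)` plus a geometric
  bound on the remaining tail;
- exponential `p(k) = (1 − e^−λ)·e^{−λ(k − xmin)}`, the closed form of the
  same discretisation (a shifted geometric law).

Fitting is bounded maximum likelihood: α ∈ (1, 20] by scalar search,
(μ, σ) ∈ [−20, 15] × [10⁻³, 25] by L-BFGS-B started at the log-moment
estimates, λ ∈ (10⁻⁶, 20] by scalar search. `xmin = "auto"` scans candidate
values (the unique observed sizes) and keeps the one minimising the
Kolmogorov–Smirnov distance between empirical and fitted tail CDFs, then
refits. Constant tails raise a degenerate-data error. An estimate pinned at a
search bound is returned with an explicit flag on the fit rather than raised:
the flagged case that matters in practice is the lognormal on genuinely
power-law data, whose likelihood keeps improving as μ → −∞ (the mimicry
regime); the bound-constrained fit is exactly the comparator the model
comparison needs.

Vuong's test compares two fits on the identical observation vector:
`z = mean(dᵢ)·√n / sd(dᵢ)` with `dᵢ` the per-observation log-likelihood
differences, two-sided normal p-value, verdict at 0.05. `compare_models`
fits all three models at a common xmin taken from the power-law auto scan
and reports pairwise results.

One behaviour worth stating plainly: on lognormal samples the auto-xmin scan
typically lands deep in the tail, where a truncated lognormal and a power
law are genuinely indistinguishable — the comparison then reports exactly
that, which mirrors what such comparisons report on real family-size data
for the largest classes. Discrimination is recovered by comparing at the
full support (`xmin = 1`), which is how the recovery benchmarks exercise the
test. Bootstrap stability is nonparametric (resample, refit, 2.5/97.5
percentile intervals, default 1,000 replicates; degenerate resamples are
counted and reported, > 50% failures is an error; per-replicate seeds are
retained).

## Taxonomic specificity and lifestyle exclusivity

Each family is a **singleton** (one member), **genus-specific** (≥ 2
members, one genus) or **multi-genus**. The three categories partition all
families, hence the chi-square against a null proportion vector (uniform by
default, configurable) always has df = 2. A family is lifestyle-exclusive
when it spans at least `min_genera` (default 3) distinct entomopathogenic
genera and contains no member from any other genus; the entomopathogenic
genus set defaults to {Metarhizium, Beauveria, Cordyceps, Hirsutella,
Tolypocladium, Purpureocillium, Akanthomyces} and is editable. Genus
co-occurrence counts, for each unordered genus pair, the exclusive families
containing both.

## Expression scoring

Size factors are DESeq2-style median-of-ratios: genes with any zero are
excluded from the geometric-mean reference; a sample's factor is the median
ratio of its counts to the reference. The transform is
`log2(count/sf + 1)` — monotone and variance-flattening. It is a deliberate
simplification of a dispersion-trend variance-stabilising transform: it
preserves ranks and condition differences, which is all the induction
scoring consumes, but its variance flattening at very low counts is cruder.
The induction score of a gene is mean transformed expression in infection
samples minus the mean in saprophytic controls, reported pooled and per
host; a BGC's score is the mean over its genes, with backbone genes flagged
(and marked `*` in heatmap exports). No significance threshold is imposed on
scores; they are effect sizes, left to the caller to threshold.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the analysis assumes:
ancestral families with prototype architectures, heavy-tailed family sizes,
genus-faithful member allocation, token/sequence mutation, and per-genome
orphans. Defaults describe a Hypocreales-like survey scaled to bench size:
12 genera (half entomopathogenic, drawn from the real genus names), 4
genomes per genus, 40 ancestral families, lognormal(μ=1.4, σ=0.8) family
sizes (mean ≈ 6 members, matching a large-survey families-to-clusters
ratio), class probabilities proportional to the published seven-class
composition of a 12,968-cluster inventory, domain alphabet 200, prototype
length 5–15, sequence length 30 over the 20-letter residue alphabet,
mutation rate 0.02, indel rate 0.01, one orphan per genome in expectation,
genus fidelity 0.85, MiBIG-hit rate 0.03.

Prototypes of the same class are rejection-sampled (tokens drawn without
replacement) until their Jaccard distance to every existing same-class
prototype is ≥ 0.8, so between-family distances stay high and ground-truth
recovery is well-posed; orphan architectures are sampled under the same
separation constraint. Genome sizes get a weak positive link to BGC count
(30 Mb + 0.15 Mb per BGC + Gaussian noise), enough for the genome-size
association to have signal without dominating it.

What the generator does **not** emulate: phylogenetic gain/loss on a tree,
horizontal transfer, correlated domain evolution, class-dependent
architecture styles, and any real within-family identity threshold (the
mutation rate is exposed instead of asserted). Passing recovery benchmarks
therefore show the pipeline is correct and well-calibrated under its own
assumptions — not that real inventories satisfy those assumptions.

`simulate_counts_matrix` draws negative-binomial counts (variance
m + d·m²) with lognormal gene baselines (median 200) and multiplies induced
genes' means by `2^log2fc` in infection samples; the balanced default design
is 2 hosts × 2 timepoints × 3 replicates of infection against 12 controls.

## Problem sizes

The bundled benchmarks use inventories of ≈ 200–260 BGCs (50 replicate
datasets for the monotonicity suite), 10,000 draws for tail-parameter
recovery, 200 bootstrap replicates for the stability interval, and 500-gene
× 18-sample count matrices — sizes at which every check runs in seconds
while estimator error is well inside the asserted bands.

## Known limitations

- The distance is architecture-based only; no HMM domain calling, anchor
  boosting, or glocal alignment modes.
- Families are plain connected components; no clan-level second pass.
- The lognormal normalisation constant is summed numerically; for σ far
  above the search bounds the truncation correction would degrade, which the
  bounds themselves prevent.
- The VST stand-in under-stabilises genes with single-digit counts; very
  low-expression BGCs get noisier induction scores.
- Auto-xmin follows the KS-minimisation convention and inherits its
  tendency to pick deep tails on non-power-law data (reported honestly by
  the comparison, see above).
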