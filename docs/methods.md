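# Methods

## Data model and filtering

The working unit is a binary genus × sample occurrence matrix `X_ia` with a
two-level environmental annotation per sample (environment type, and the
finer subtype nested within it).  Margin filtering removes samples with
fewer than 5 genera and genera present in fewer than 5 samples.  Because
each removal can invalidate the other constraint, the filter iterates to a
fixed point, so the returned table satisfies both constraints
simultaneously; single-pass behaviour is available via `iterate=False`.
The fixed-point choice removes any dependence on the order in which the two
rules are applied.

## Null model of occurrence

Within one environment subtype, occurrences are modelled as independent
Bernoulli cells with `π_ia = logistic(α_i + β_a)`, the maximum-entropy
distribution on binary matrices whose expected row and column totals match
the observed ones.  `α` and `β` are fitted by alternating per-row/per-column
Newton steps to a relative margin tolerance of 1e-6 (default cap 1000
sweeps; non-convergence raises an error reporting the worst residual).
Saturated margins are peeled off exactly beforehand: all-zero rows/columns
get `π = 0`, full rows/columns `π = 1`, so degenerate tables (e.g. all
ones) are handled without numerical overflow.  An environment's probability
matrix is the column-wise concatenation of its subtypes' fits, which is what
lets the downstream scores control for subtype-specific occupancy structure.

## Aggregation scores and calibration

For nodes *u, v* with presence vectors over *M* samples and observed
co-occurrence count *N*, the aggregation score is `S = −log P(X ≥ N)` with
`X` Poisson-binomial, per-sample success `π_ua·π_va` (independence under
the null).  The tail is computed by exact dynamic programming over the
count distribution and summed from the top of the pmf, so tiny tails are
not lost to cancellation; tails are clamped at 1e-300 to keep `S` finite.
The inclusive tail `P(X ≥ N)` is used so the observed configuration itself
has non-zero probability; the strict variant is a configuration switch.
A vectorized all-pairs variant computes each pair's survival table once and
reuses it across every ensemble matrix — valid because fixed-margin
randomization leaves each genus's occupancy, and hence the pair's
probability vector, unchanged.

Raw scores grow with how cosmopolitan the two members are, so significance
is judged against null pairs of similar cosmopolitanism.  The null ensemble
(default 1000 matrices per environment; smaller in desk-scale runs) is
drawn by curveball trades, which preserve row and column totals exactly;
burn-in defaults to 5× the number of ones, with one thinning sweep
(number-of-genera trades) between draws.  Pairs are binned by quantiles of
`c = log(n_u·n_v + 1)` (default 20 bins); bins with fewer than 50 null
scores or zero variance are merged with their lower neighbour, and the
outermost bins are unbounded, so every conceivable pair — including merged
and residual nodes with reduced occupancy — maps to exactly one bin.  Null
scores are standardized per bin and the significance cutoff is the smallest
observed null Z whose exceedance fraction is at most the target false
positive rate (default 1e-4), with ties resolved by counting.  The null Z
distribution is strongly heavy-tailed (sparse pairs take few discrete score
values, so their bins have small variance and occasional large
standardized excursions); the empirical cutoff absorbs this by
construction, which is why it can sit far above the Gaussian 1e-4 quantile.

## Conditional clustering and consensus

Each run starts from one node per genus.  While any pair of active nodes is
significant (Z above the cutoff) and co-occurs in more than 5 samples
(strict reading, i.e. ≥ 6; configurable), one eligible pair is selected
with probability proportional to its Z — the simplest weighting consistent
with "higher scores are more likely" — and merged:

    X_k = X_i·X_j      π_k = π_i·π_j
    X_i* = X_i·(1−X_j)  π_i* = π_i·(1−π_j)   (and symmetrically for j*)

The three children partition the parents' supports exactly
(`X_k + X_i* = X_i`), each merge strictly decreases total presence mass, so
termination is guaranteed.  Residuals left with no samples are dropped.
Scores involving new nodes are recomputed from the updated vectors; the
initial null calibration's bins are reused, with nodes assigned by their
current occupancy (re-simulating a null ensemble at every iteration is
neither stated nor computationally sensible).  Because genus-level initial
pair statistics are deterministic, they are computed once and shared across
the (default 100) runs, whose seeds are spawned from one base seed.

Runs are combined by taxa content: nodes with identical taxa sets collapse
(a residual collapses with its source taxon), support counts the number of
individual networks containing a node or edge, nodes are annotated with the
environments whose runs produced them, and support < 10 is discarded.
Terminal assemblages are the multi-genus nodes without outgoing edges in
the subnetwork of edges with support > 70.  Support thresholds are counted
against total support (at most `n_runs` per environment); whether the
consensus threshold should instead be per-environment for multi-environment
assemblages is ambiguous, so the global reading is the documented default
and the threshold is configurable.

## Functional and phylogenetic summaries

A genus's core genome is the intersection of its genomes' pathway sets;
every genome in the input table is treated as eligible (completeness
screening is upstream's responsibility).  Genus-level phylogenetic
distances are medians over all cross-pairs of member species distances
(substitutions/site), with a forced zero diagonal.  Per-assemblage
summaries are averages over all unordered member pairs: Jaccard
dissimilarity between core pathway sets (pathways are sets, not fixed-length
match vectors), phylogenetic distance, plus mean core size and the pathway
union.  Assemblages with an unannotatable member raise a skip signal rather
than crash.

## Random assemblages and hypothesis tests

Four rejection-sampling generators produce size-matched random assemblages:
unconstrained (1000 replicates); same environment subtype (100); same
subtype and mean pairwise phylogenetic distance within 0.05
substitutions/site of the reference (100); same subtype and mean pathways
per genus within 20% (100).  Pools are all network genera (unconstrained)
or all genera observed in the reference's subtype.  Sampling is without
replacement, with a 10,000-attempt budget per draw; infeasible references
are skipped with a warning rather than silently relaxing the constraint.
Group distributions are compared per metric and assemblage size with
two-sided Mann-Whitney U (exact for group sizes < 20 without ties,
asymptotic with tie correction otherwise), Benjamini-Hochberg corrected
within each (metric, size) family.

## Pathway classification and auxotrophy

For each terminal assemblage, 1000 subtype- and phylogeny-matched random
assemblages are drawn with the tolerance relaxed to 0.1 substitutions/site
(the tighter 0.05 used for the redundancy report starves the sampler at
this stage; both values are configuration).  For each pathway in the pool's
core-pathway universe, with real prevalence *P* in an assemblage of size
*S*:

- **Redundant** — `P ≥ 2` and `P` strictly greater than the prevalence in
  ≥ 95% of random assemblages;
- **Specific** — `P ≥ 1` and `P` strictly smaller than in ≥ 95% of them;
- **Missing** — `P = 0` while ≥ 95% of them contain the pathway;
- **Unclassified** otherwise (ties deliberately favour Unclassified — a
  conservative one-sided empirical test).

The calls are mutually exclusive by construction.  Size-class comparisons
split assemblages at 5 members (4 and 6 runnable as alternatives) and
compare per-assemblage `Σ P / S` within each call class by rank-sum test.
The auxotroph fraction of a pathway is `1 − P/S`; per amino acid, fractions
are averaged over all terminal assemblages with ≥ 5 members and regressed
on biosynthetic cost (ordinary least squares, run with and without
tryptophan, whose tight regulation and negligible environmental leakage
decouple its auxotroph prevalence from raw cost).  The built-in cost table
is the standard published 20-amino-acid opportunity-cost set in high-energy
phosphate bonds.

## Synthetic data

The generators emulate the statistical structure the method consumes, with
ground truth for scoring recovery:

- **Occurrences** — genus occupancies Beta(0.7, 4) (most genera rare, a few
  cosmopolitan), per-sample richness effects Beta(5, 5) normalized to mean
  one, cells independent Bernoulli of the clipped product, samples laid out
  over a configurable environment hierarchy.  Margins track the drawn
  propensities by construction.
- **Plants** — within a subtype, all members of a planted set are jointly
  forced present with extra probability `q = clip((boost−1)·Π f_m, 0, 1)`
  (`f_m` = member marginal frequency there), so boost 1 is exactly the
  identity; margins are approximately restored by removing matching
  presences elsewhere (best-effort; the null model is refit on the planted
  matrix, so exactness is not required).  Conditional maps expand into
  per-subtype joint plants sharing a focal taxon.  Planting taxa whose
  subtype frequency is moderate (~0.05–0.12) matters: very common members
  saturate (`q → 1` makes the row equal the subtype indicator and the
  margin model absorbs the signal), very rare ones carry too little signal.
- **Pathways** — per-genus cores drawn from a popularity-weighted universe
  at target sizes 15–40, 1–5 genomes per genus adding genome-private noise
  pathways (which vanish from any core computed over ≥ 2 genomes); planted
  redundant/specific/missing roles are realized exactly in the cores with
  background prevalences 5% / 90% / 90%.
- **Phylogeny** — genera embedded in a latent trait space (mean separation
  ~0.25 substitutions/site), congeneric species within 0.03, so
  within-genus distances are smaller than between-genus on average.

Not emulated: relative abundances, study-level batch structure, read-level
noise, true tree-like (ultrametric) distances, and correlated pathway gain/
loss along the phylogeny.  Passing recovery tests therefore demonstrates
the statistical machinery, not robustness to those real-data complications.

## Verification scales and numerical choices

The test suite runs the statistical guarantees at desk scale: false
positive rate control at 150 genera × 250 samples with a 100-matrix
ensemble and 100 fresh matrices (≥ 10⁶ pair evaluations); planted and
conditional recovery and null specificity at 100 genera × 300 samples with
100 runs; pathway-role recovery with 60 pool genera, 5 planted assemblages
and 1000 random assemblages; report calibration over 200 simulated null
data sets (the asymptotic U test is mildly liberal at group size 25, so the
acceptance band is alpha ± 50%).  `scripts/acceptance.py` recomputes the
false-positive-rate guarantee at 200 × 300 with a 200-matrix ensemble.
Floating-point choices: probability clipping to [0, 1], tail clamping at
1e-300, survival tables capped at 1, exact integer co-occurrence counts via
matrix products.  One check cannot pass without external data: reproducing
the published 966-genus / 5369-sample scale of the filtered cross-biome
database requires its SQL dump, which is not redistributable with this
package.

## Known limitations

- The per-subtype null model controls environment- but not study-level
  biases; associations remain inferences conditional on the inputs and the
  null.
- The empirical Z cutoff inherits Monte-Carlo noise of order
  `1/√(n_pairs · n_null)`; with few genera or tiny ensembles it is
  unstable, and the package errors rather than guessing when all score
  variance is degenerate.
- Merged-node Z-scores reuse the genus-level calibration bins; a dedicated
  null for composite nodes is not simulated.
- GraphML export flattens taxa sets to `|`-joined strings; round-tripping
  relies on genus labels not containing the separator.
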