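# Methods

`traitclust` asks a single question of a trait database: how much of the
multivariate trait variation among plant species is explained by an a
priori classification into functional groups, compared with the best
post hoc classification statistical clustering can find?  This note
records the models, conventions and design choices behind each stage.

## Data model and cleaning

Input is a long-format record table (one measurement per row: species,
trait, value, unit, optional coordinates/site/year, source).  Cleaning
mirrors the conventions of large compiled trait databases:

1. **Exact duplicates** — identical (species, trait, value, unit,
   source) tuples collapse to one record.  Near-duplicates are kept:
   there is no defensible fuzziness rule for compiled data.
2. **Erroneous values** — values ≤ 0 are removed (all supported traits
   are strictly positive quantities).
3. **Outlier filter** — per species × trait, records more than 4 sample
   standard deviations from the species mean are removed.  The filter
   runs on **log10 values** (the traits are log-normal, so SDs on the
   raw scale would be dominated by the heavy right tail), in a **single
   pass** with the candidate point included in its own mean/SD, and is
   skipped when a species × trait cell has fewer than 3 records (the
   sample SD is unstable) or zero SD.  A single-pass k-SD filter is not
   idempotent in pathological configurations (removing one outlier can
   expose another); on realistically generated data a second pass
   removes nothing, which the suite checks.
4. **Seed mass review** — seed mass is especially prone to measurement
   and transcription error, so records beyond 3 SDs are *flagged* in
   the provenance report for manual review, never silently dropped.

Every removal is itemized in a provenance report; record counts are
conserved (kept + removed = input).

## Species × trait matrix

Pipeline order: log10-transform each record → aggregate per species ×
trait (mean of log values by default, i.e. geometric-mean-like; 25th or
75th percentile variants, with linear interpolation at index (n−1)q,
probe sensitivity to within-species variation) → retain complete cases
(species with every requested trait) → scale each trait column across
species.

Scaling modes: `minmax` (default) maps each trait affinely onto [0, 1];
`zscore` centers to mean 0, SD 1.  A z-score followed by a min–max
rescale is *identical* to a plain min–max (both are affine maps pinning
the column minimum to 0 and maximum to 1), so only these two genuinely
distinct modes are offered.  The applied affine transform and log base
are stored per trait, so aggregated log values are exactly recoverable
(round-trip tested to 1e−9).  Log base 10 throughout; any fixed base
differs only by a per-trait affine factor that min–max scaling absorbs.

Column subsets for the economic ({SLA, LDMC, leaf N}) versus size
({plant height, seed mass, leaf area}) analyses reuse the full-matrix
scaling rather than rescaling within the subset, so subset distances
live in the same space as the full analysis.

## PERMANOVA

One-way PERMANOVA on Euclidean distances:
SS_T = Σ_{i<j} d²_ij / n, SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g,
SS_A = SS_T − SS_W, pseudo-F = (SS_A/(a−1)) / (SS_W/(n−a)),
R² = SS_A/SS_T.  For Euclidean distances this is algebraically
identical to classical one-way (multivariate) ANOVA — the identity
Σ_{i<j} d² = n·ΣΣ(x−x̄)² — which the test suite verifies against a
sums-of-squares oracle to 1e−9.

Significance comes from permuting group labels over points with the
distance matrix fixed.  The p estimator is the +1/+1 form
p = (1 + #{permuted ≥ observed}) / (1 + n_perm), so p is never 0 and
the smallest reportable value at 999 permutations is 0.001.  When the
number of *distinct* label arrangements is ≤ 10,000 the full
permutation distribution is enumerated instead (p is then the exact
tail proportion; the observed arrangement is one of them).  Permuted
statistics are compared on R², a strictly increasing function of
pseudo-F at fixed degrees of freedom, which avoids ±inf arithmetic when
SS_W = 0.  Degenerate inputs: all points identical → R² defined as 0,
F undefined, result flagged; SS_W = 0 with SS_T > 0 → R² = 1, F = +inf.

Two identities anchor the implementation: the mean of R² over the full
permutation distribution equals (a−1)/(n−1) exactly, and under
exchangeable data the test holds its nominal size (checked at α = 0.05
over 2,000 null simulations).

## PCA and per-trait tests

PCA is an eigendecomposition of the covariance of the centered, already
column-scaled matrix (not re-standardized to correlation — the columns
are deliberately on a common scale).  Component signs are fixed by
making each loading column's largest-magnitude entry positive.

Per-trait group differences use two-sided rank-sum tests on
species-level aggregated values (one value per species).  When both
groups have ≤ 10 values the two-sided p is computed by exhaustive
enumeration of rank assignments using midranks, so ties are handled
exactly and identical multisets give p = 1; larger groups use the
tie-corrected normal approximation.  Holm adjustment across pairs is
optional.  Only unpaired rank-sum tests are offered: the compared
groups are disjoint species sets, so a paired signed-rank test has no
coherent interpretation here.

## Clustering

**k-means** (Lloyd, k-means++ seeding, best of n_init = 100 restarts by
inertia, max 300 iterations) is delegated to scikit-learn and is
deterministic given a seed; labels are renumbered by order of first
appearance so output does not depend on library internals.

**Ward** agglomeration is implemented directly so its tie-break rule is
explicit: initial merge costs between singletons are ‖x_i − x_j‖²/2
(the increase in total within-cluster SS of fusing them), updated after
each merge by the Lance–Williams recurrence; among cost-ties the
lexicographically smallest (cluster-id, cluster-id) pair merges first,
with leaves numbered in species order and new clusters in formation
order.  Merge costs are recorded as ΔSS (scipy's "ward" heights h
satisfy ΔSS = h²/2, the cross-check used in the tests); they are
non-decreasing, and their total equals the total SS of the centered
matrix (conservation, tested to 1e−8).  Cutting the tree after n−k
merges yields the k-cluster partition; cutting a zero-cost (all points
identical) tree is allowed.

k is always fixed to the group scheme under comparison (4, 6 or 7);
the package deliberately offers no internal k selection.

## Partition agreement

Cluster labels are arbitrary, so a clustering is compared to the
reference groups through the confusion matrix and the one-to-one label
matching that maximizes co-classified species — exhaustive permutation
search when min(rows, cols) ≤ 8 (ties: first in lexicographic order),
Hungarian assignment otherwise; the two routes agree on the optimum
value (tested on 1,000 random matrices).  When a clustering has more
labels than the reference, unmatched labels contribute nothing.

"All-methods" consistency is reference-anchored: a species counts when
*every* comparison partition maps it to its reference group under that
partition's own optimal matching (the intersection of the pairwise
consistent sets).  The k-means↔Ward column is a direct pairwise
matching between the two clusterings, with per-group breakdowns still
reported by functional group.

Abundance weighting uses the plot-level cover table: per plot the most
recent year, summed to site level per species, restricted to species
with trait data; each site contributes the cover share of consistent
species, and sites are averaged unweighted (a pooled mode that sums
cover across sites first is available as a config switch; the per-site
mean is the default reading of site-level aggregation).

## Trait-combination resampling

Trait subsets have unequal complete-case pools, so for each of the 2⁶−1
subsets the analysis draws a fixed number of species (default 295)
without replacement from that subset's pool and averages the group R²
over 999 replications (per-subset seeds derived independently, so
subsets redraw independently).  Standardization is computed once on the
full pool, then rows are subsampled.  Per replication, R² is computed
from coordinates (one-way multivariate sums of squares about group
means) — for Euclidean distances exactly the PERMANOVA R², verified
against the distance route in the tests — with no permutations, since
only the point estimate is averaged.  Pools not exceeding the draw size
use the whole pool and are flagged degenerate (replicate SD is then 0
by construction).  Singleton subsets are included by default
(`min_size = 1`).  Classes: economic-only, size-only, mixed, plus
contains-LDMC and contains-height-or-seed-mass groupings.

## Synthetic data generator

The generator emulates the statistical shape of a compiled tundra trait
database, with every parameter explicit:

- log10(value) = group mean + species offset + record noise, with
  species offsets ~ N(0, σ_between) per trait and record noise
  ~ N(0, σ_within); values are 10^(log value), hence log-normal.
- Default archetypes (4 groups × 6 traits, log10 scale, height in cm,
  seed mass in mg, leaf area in mm², SLA in mm²/mg, LDMC in g/g, leaf N
  in mg/g) place evergreen shrubs at the conservative end (lowest SLA
  and leaf N, highest LDMC) and forbs at the acquisitive end, with
  group separation stronger on economic than size traits.
- Defaults: 4 groups × 100 species, σ_between = 0.4, σ_within = 0.12,
  3–12 records per species, 5% per-trait missingness — chosen so the
  six-trait complete-case pool is ≈ 295 species and the planted groups
  explain roughly a fifth of trait variation, the overlap regime this
  kind of biome-scale analysis operates in.
- Cover: per site × plot × year, a symmetric Dirichlet draw over all
  species (concentration `abundance_shape`, default 0.3) scaled to 100%
  cover; small concentrations give realistically skewed rank-abundance
  curves.  This is the simplest skew-controllable choice; no attempt is
  made to fit a particular rank-abundance model.

`expected_separation_r2` converts a config into the large-sample R² on
the unscaled log matrix: Σ_t V_between,t / Σ_t (V_between,t + σ²_between,t
+ σ²_within,t · E[1/m]), with V_between the population variance of the
group means and m the per-species record count.  It is exact for
equal-scale traits without rescaling (verified within ±0.05 at 1,000
species) and approximate after [0, 1] rescaling, which reweights
traits.

What the generator does **not** emulate: phylogenetic signal, spatial
or trait–environment structure, correlated trait deviations within
species, non-normal log-scale tails, and real taxonomic noise.  Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to every property of field data.

## Reproducibility

All randomness (permutations, k-means restarts, resampling draws,
simulation) flows through seeded NumPy generators; nothing reads the
clock or OS entropy.  A run-level seed is expanded into independent
per-stage seeds via `SeedSequence([seed, stage_index])` reduced mod
2³¹, so any stage can be reproduced in isolation.  Full-pipeline output
is a pure function of (inputs, config, seed); rerunning a config yields
byte-identical summaries.

Default problem sizes (299 permutations would be statistically adequate
for most uses; the defaults keep the study's 999 permutations and 999
replications, ~20 s end-to-end for the default synthetic study on one
core) are package choices recorded in `AnalysisConfig`.

## Known limitations

- One-way designs only: no multi-factor or nested PERMANOVA, no strata,
  and no dispersion (betadisper-style) test — significant PERMANOVA R²
  can reflect dispersion differences as well as location shifts.
- Complete-case matrices only; no imputation or gap-filling, so species
  selection covaries with trait availability.
- The exhaustive rank-sum enumeration is exact but limited to groups of
  ≤ 10 values; beyond that the normal approximation is used.
- Unit handling is a declared per-trait expectation, not a conversion
  system; mixed-unit inputs must be harmonized upstream.
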