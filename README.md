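# traitclust

Do a priori plant functional groups — evergreen shrubs, deciduous
shrubs, graminoids, forbs — actually capture how species differ in
their traits?  `traitclust` is a pipeline for answering that question
with a compiled trait database: it cleans long-format trait records,
builds a standardized species × trait matrix, partitions multivariate
trait variance over any species classification with PERMANOVA, finds
the best *post hoc* classification by k-means and Ward clustering, and
scores how consistently the a priori and data-driven classifications
place species — overall, per group, and weighted by community abundance
from plot-level cover data.

It is aimed at trait-based community ecologists working with compiled
databases (TRY-style long tables plus vegetation-survey cover data) who
want the full analysis — cleaning rules, variance partitioning,
clustering, label matching, trait-subset resampling — reproducible from
one seeded config.

## The statistics at the core

For species trait profiles x_i and a partition into a groups, one-way
PERMANOVA on Euclidean distances d_ij partitions

    SS_T = Σ_{i<j} d²_ij / n,   SS_W = Σ_g Σ_{i<j∈g} d²_ij / n_g,
    R² = (SS_T − SS_W) / SS_T,
    pseudo-F = ((SS_T − SS_W)/(a−1)) / (SS_W/(n−a)),

with significance from permuting group labels (999 permutations,
p = (1 + #{F* ≥ F}) / (1 + 999)).  Post hoc partitions come from
k-means (best of 100 k-means++ restarts) and Ward agglomeration
(minimum ΔSS merges) at the same k as the functional-group scheme.
Agreement between partitions is the maximum number of co-classified
species over one-to-one label matchings (an assignment problem), giving
the proportion of consistently classified species and its
abundance-weighted analogue.  Because trait subsets have unequal
species pools, per-subset explanatory power is compared by drawing a
fixed number of species (295) per subset and averaging R² over 999
replications.

A synthetic-data generator with planted group structure (log-normal
traits, configurable between-group separation, within-species noise,
missingness, skewed Dirichlet abundances) stands in for a real
database, so the whole pipeline is testable end to end with known
ground truth.  See `docs/methods.md` for conventions and assumptions.

## Worked example

```python
from traitclust import (
    SyntheticConfig, generate_dataset, clean_dataset, build_matrix,
    euclidean_distances, permanova, kmeans_cluster, ward_linkage,
    cut_tree, consistency, CORE_TRAITS,
)

ds, scheme, cover, truth = generate_dataset(SyntheticConfig(seed=7))
ds = clean_dataset(ds)
m = build_matrix(ds, list(CORE_TRAITS))        # 297 complete-case species
dm = euclidean_distances(m)

fg = permanova(dm, scheme.to_partition(), n_permutations=999, seed=1)
km = kmeans_cluster(m, k=4, seed=1)
hca = cut_tree(ward_linkage(m), k=4)
print(f"functional groups  R2={fg.r_squared:.3f}  p={fg.p_value:.3f}")
print(f"k-means            R2={permanova(dm, km.partition, 0).r_squared:.3f}")
print(f"Ward               R2={permanova(dm, hca, 0).r_squared:.3f}")

cons = consistency(scheme.to_partition(), {"kmeans": km.partition, "hca": hca},
                   cover=cover, species_with_traits=set(m.species))
for name, res in cons.items():
    print(f"{name:12s} consistent: {100 * res.proportion_overall:.1f}% of species, "
          f"{100 * res.abundance_weighted_proportion:.1f}% of cover")
```

Output:

```
functional groups  R2=0.194  p=0.001
k-means            R2=0.356
Ward               R2=0.302
kmeans       consistent: 54.2% of species, 54.4% of cover
hca          consistent: 52.5% of species, 52.7% of cover
all_methods  consistent: 44.4% of species, 43.9% of cover
```

Read: the a priori functional groups explain ~19% of multivariate trait
variation among these species, while the best trait-based 4-group
classifications explain 30–36%; only ~44% of species land in the same
group under every method, and those species carry a similar share of
total vegetation cover.

The same workflow runs from the shell on CSV inputs or a synthetic
config:

```bash
traitclust all --config demo.yml --seed 7 --out results/
# or stage by stage:
traitclust simulate --config demo.yml --out results/
traitclust clean    --config demo.yml --out results/
traitclust matrix   --config demo.yml --out results/
traitclust permanova --config demo.yml --out results/ --traits SLA,LDMC,leaf_N
traitclust cluster  --config demo.yml --out results/ --k 4
traitclust compare  --config demo.yml --out results/
traitclust combos   --config demo.yml --out results/
```

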