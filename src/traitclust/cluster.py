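"""Post hoc classification of species: k-means and Ward agglomeration.

Both methods operate on the standardized trait matrix.  k-means (Lloyd
with k-means++ seeding and many restarts, via scikit-learn) assigns
species to groups by multivariate distance from group means; Ward's
method builds a hierarchy by repeatedly merging the pair of clusters
whose fusion least increases the total within-cluster sum of squares
(the merge cost recorded here is that increase, delta-SS).  Ties in the
merge cost are broken deterministically by the lexicographically
smallest cluster-id pair so the tree is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import ValidationError
from .matrix import TraitMatrix


@dataclass
class Partition:
    """Assignment of species to labeled groups (a priori or clustered)."""

    labels: pd.Series  # index species_name -> group label
    method: str = "a_priori"  # a_priori | kmeans | hca

    @property
    def k(self) -> int:
        return self.labels.nunique()

    @property
    def species(self) -> list:
        return list(self.labels.index)

    def relabeled(self, mapping: dict) -> "Partition":
        return Partition(labels=self.labels.map(mapping), method=self.method)

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("label").rename_axis("species_name").reset_index()


@dataclass
class KmeansFit:
    partition: Partition
    centroids: pd.DataFrame  # cluster label x trait
    inertia: float
    n_init: int
    seed: int | None


def kmeans_cluster(
    m: TraitMatrix,
    k: int,
    n_init: int = 100,
    max_iter: int = 300,
    seed: int | None = None,
) -> KmeansFit:
    """k-means clustering of species in standardized trait space.

    Best of ``n_init`` k-means++ restarts by within-cluster sum of squares
    (inertia); deterministic given ``seed``.  Cluster labels are integers
    0..k-1, renumbered by each cluster's smallest species index so labels
    are stable across library versions.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(m.species):
        raise ValidationError(f"k={k} exceeds number of species ({len(m.species)})")
    from sklearn.cluster import KMeans

    x = m.to_numpy()
    fit = KMeans(
        n_clusters=k, n_init=n_init, max_iter=max_iter, random_state=seed,
        init="k-means++", algorithm="lloyd",
    ).fit(x)
    raw = fit.labels_
    order = {}
    for lab in raw:  # renumber by order of first appearance
        if lab not in order:
            order[lab] = len(order)
    labels = pd.Series([order[lab] for lab in raw], index=m.species)
    cent = fit.cluster_centers_[sorted(range(k), key=lambda i: order.get(i, k))]
    return KmeansFit(
        partition=Partition(labels=labels, method="kmeans"),
        centroids=pd.DataFrame(cent, columns=m.traits),
        inertia=float(fit.inertia_),
        n_init=n_init,
        seed=seed,
    )


@dataclass
class LinkageTree:
    """Ward merge sequence: at each step the two merged clusters and delta-SS."""

    merges: list = field(default_factory=list)  # dicts: step, members_a, members_b, delta_ss
    leaves: list = field(default_factory=list)  # species in index order

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def merge_costs(self) -> np.ndarray:
        return np.array([m["delta_ss"] for m in self.merges])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "step": m["step"],
                "members_a": "|".join(str(self.leaves[i]) for i in sorted(m["members_a"])),
                "members_b": "|".join(str(self.leaves[i]) for i in sorted(m["members_b"])),
                "delta_ss": m["delta_ss"],
            }
            for m in self.merges
        ]
        return pd.DataFrame(rows)


def ward_linkage(m: TraitMatrix) -> LinkageTree:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Initial merge costs between singletons i, j are ||x_i - x_j||^2 / 2
    (the SS increase of fusing them); after each merge the costs to the
    new cluster follow the Lance-Williams update for Ward.  Cost ties are
    broken by the smallest (cluster_id_a, cluster_id_b) pair, where leaves
    get ids 0..n-1 in species order and merged clusters get ids n, n+1,
    ... in formation order.
    """
    n = len(m.species)
    if n < 2:
        raise ValidationError("need at least 2 species")
    x = m.to_numpy()
    total = 2 * n - 1
    # cost[i, j] = delta-SS of merging clusters i and j; inf if inactive
    cost = np.full((total, total), np.inf)
    cost[:n, :n] = squareform(pdist(x, metric="sqeuclidean")) / 2.0
    np.fill_diagonal(cost, np.inf)
    sizes = np.zeros(total, dtype=int)
    sizes[:n] = 1
    members: list[set | None] = [{i} for i in range(n)] + [None] * (n - 1)
    active = np.zeros(total, dtype=bool)
    active[:n] = True

    merges = []
    for step in range(n - 1):
        ids = np.flatnonzero(active)
        sub = cost[np.ix_(ids, ids)]
        cmin = sub.min()
        ii, jj = np.nonzero(sub <= cmin)  # exact ties only
        pairs = sorted(
            (int(ids[a]), int(ids[b])) for a, b in zip(ii, jj) if ids[a] < ids[b]
        )
        i, j = pairs[0]
        new = n + step
        merges.append(
            {"step": step, "members_a": members[i], "members_b": members[j],
             "delta_ss": float(cost[i, j])}
        )
        members[new] = members[i] | members[j]
        sizes[new] = sizes[i] + sizes[j]
        active[i] = active[j] = False
        active[new] = True
        ks = np.flatnonzero(active[:new])
        si, sj, sk = sizes[i], sizes[j], sizes[ks]
        cost[new, ks] = cost[ks, new] = (
            (si + sk) * cost[i, ks] + (sj + sk) * cost[j, ks] - sk * cost[i, j]
        ) / (si + sj + sk)

    return LinkageTree(merges=merges, leaves=list(m.species))


def cut_tree(tree: LinkageTree, k: int) -> Partition:
    """Cut a Ward tree into k clusters (the clusters after n-k merges).

    Labels are integers 0..k-1 ordered by each cluster's smallest leaf
    index.  Cutting a tree whose merge costs are all zero (identical
    points) is permitted; the result carries ``degenerate`` information
    only through the tree's costs.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range [1, {n}]")
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for merge in tree.merges[: n - k]:
        a = find(min(merge["members_a"]))
        b = find(min(merge["members_b"]))
        parent[max(a, b)] = min(a, b)

    roots = [find(i) for i in range(n)]
    order = {}
    for r in roots:
        if r not in order:
            order[r] = len(order)
    labels = pd.Series([order[r] for r in roots], index=tree.leaves)
    return Partition(labels=labels, method="hca")
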