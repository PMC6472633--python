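"""Distance matrices, one-way PERMANOVA, PCA and pairwise rank tests.

PERMANOVA partitions the total sum of squared inter-point distances into
between- and within-group components and tests group significance by
permuting group labels over points while holding the distance matrix
fixed.  For Euclidean distances on a 1-column matrix this reduces exactly
to classical one-way ANOVA (the identity sum_{i<j} d_ij^2 = n * SS), which
the test suite exploits as an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io import ValidationError
from .matrix import TraitMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with species labels."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.values = d

    def __len__(self) -> int:
        return len(self.labels)


def euclidean_distances(m: TraitMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distances between species trait profiles."""
    if len(m.species) < 2:
        raise ValidationError("need at least 2 species")
    return DistanceMatrix(
        labels=m.species, values=squareform(pdist(m.to_numpy(), metric="euclidean"))
    )


@dataclass
class PermanovaResult:
    ss_total: float
    ss_within: float
    ss_between: float
    df_between: int
    df_within: int
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = "sampled"  # "sampled" | "enumerated" | "none"
    degenerate: bool = False
    permuted_r2: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "ss_total": self.ss_total,
            "ss_within": self.ss_within,
            "ss_between": self.ss_between,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "pseudo_f": self.pseudo_f,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "method": self.method,
        }


def _group_codes(dm: DistanceMatrix, partition) -> np.ndarray:
    """Align a partition (Partition, Series, or mapping) to the matrix labels."""
    from .cluster import Partition

    if isinstance(partition, Partition):
        labels = partition.labels
    elif isinstance(partition, pd.Series):
        labels = partition
    else:
        labels = pd.Series(dict(partition))
    missing = [s for s in dm.labels if s not in labels.index]
    if missing:
        raise ValidationError(f"partition does not cover: {missing[:5]}...")
    aligned = labels.reindex(dm.labels)
    codes, _ = pd.factorize(aligned)
    return codes


def _ss_within(d2: np.ndarray, codes: np.ndarray, a: int) -> float:
    ssw = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def _n_distinct_arrangements(counts: np.ndarray) -> float:
    n = int(counts.sum())
    out = math.factorial(n)
    for c in counts:
        out //= math.factorial(int(c))
    return out


def permanova(
    dm: DistanceMatrix,
    partition,
    n_permutations: int = 999,
    seed: int | None = None,
    enumerate_threshold: int = 10_000,
    return_permuted: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within sums the analogous quantity
    within each group; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a));
    R^2 = SS_between / SS_total.  The permutation p-value uses the +1/+1
    estimator p = (1 + #{permuted R^2 >= observed}) / (1 + n_permutations),
    so p > 0 always; when the number of distinct label arrangements is at
    most ``enumerate_threshold`` the full permutation distribution is
    enumerated instead and p is the exact tail proportion (the observed
    arrangement is one of them).  Permuted statistics are compared on R^2,
    which is a strictly increasing function of pseudo-F for fixed degrees
    of freedom.

    Degenerate cases: all points identical (SS_total = 0) yields R^2 = 0
    and undefined F, flagged; SS_within = 0 with SS_total > 0 yields
    R^2 = 1 and F = +inf.
    """
    codes = _group_codes(dm, partition)
    n = len(dm)
    counts = np.bincount(codes)
    a = len(counts)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < 1:
        raise ValidationError("every group needs at least one member")

    d2 = dm.values.astype(float) ** 2
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _ss_within(d2, codes, a)
    ss_between = ss_total - ss_within
    df_between, df_within = a - 1, n - a

    if ss_total <= 0:
        return PermanovaResult(
            ss_total=0.0, ss_within=0.0, ss_between=0.0,
            df_between=df_between, df_within=df_within,
            pseudo_f=float("nan"), r_squared=0.0, p_value=1.0,
            n_permutations=0, seed=seed, method="none", degenerate=True,
        )

    r2 = ss_between / ss_total
    if ss_within == 0:
        f = float("inf")
    else:
        f = (ss_between / df_between) / (ss_within / df_within)

    perm_r2 = None
    if n_permutations and n_permutations > 0:
        n_distinct = _n_distinct_arrangements(counts)
        if n_distinct <= enumerate_threshold:
            from sympy.utilities.iterables import multiset_permutations

            perm_r2 = np.empty(n_distinct)
            base = np.repeat(np.arange(a), counts)
            for i, arrangement in enumerate(multiset_permutations(list(base))):
                c = np.asarray(arrangement)
                ssw = _ss_within(d2, c, a)
                perm_r2[i] = (ss_total - ssw) / ss_total
            p = float(np.mean(perm_r2 >= r2 - 1e-12))
            method = "enumerated"
            n_used = int(n_distinct)
        else:
            rng = np.random.default_rng(seed)
            perm_r2 = np.empty(n_permutations)
            for i in range(n_permutations):
                c = rng.permutation(codes)
                ssw = _ss_within(d2, c, a)
                perm_r2[i] = (ss_total - ssw) / ss_total
            p = (1.0 + np.sum(perm_r2 >= r2 - 1e-12)) / (1.0 + n_permutations)
            method = "sampled"
            n_used = n_permutations
    else:
        p, method, n_used = float("nan"), "none", 0

    return PermanovaResult(
        ss_total=float(ss_total), ss_within=float(ss_within),
        ss_between=float(ss_between), df_between=df_between, df_within=df_within,
        pseudo_f=float(f), r_squared=float(r2), p_value=float(p),
        n_permutations=n_used, seed=seed, method=method,
        permuted_r2=perm_r2 if return_permuted else None,
    )


def coordinate_r2(x: np.ndarray, codes: np.ndarray) -> float:
    """One-way multivariate R^2 from coordinates (sums of squares about means).

    Equals PERMANOVA R^2 on Euclidean distances of ``x`` (the identity
    sum_{i<j} d_ij^2 = n * sum_i ||x_i - mean||^2 applied per group).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    sst = ((x - x.mean(axis=0)) ** 2).sum()
    if sst <= 0:
        return 0.0
    ssw = 0.0
    for g in np.unique(codes):
        xg = x[codes == g]
        ssw += ((xg - xg.mean(axis=0)) ** 2).sum()
    return float(1.0 - ssw / sst)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # species x component
    loadings: pd.DataFrame  # trait x component
    variance_fraction: np.ndarray


def pca(m: TraitMatrix) -> PCAResult:
    """PCA of the (already column-scaled) trait matrix, on the covariance.

    Columns are centered but not re-standardized, since they are already on
    a common scale.  Component signs are fixed by making each loading
    column's largest-magnitude entry positive, so output is deterministic.
    """
    if len(m.species) < 3 or len(m.traits) < 2:
        raise ValidationError("PCA needs >= 3 species and >= 2 traits")
    from sklearn.decomposition import PCA as _PCA

    x = m.to_numpy()
    ncomp = min(x.shape)
    fit = _PCA(n_components=ncomp, svd_solver="full")
    scores = fit.fit_transform(x)
    loadings = fit.components_.T  # trait x component, orthonormal columns
    for j in range(ncomp):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    comps = [f"PC{j + 1}" for j in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.species, columns=comps),
        loadings=pd.DataFrame(loadings, index=m.traits, columns=comps),
        variance_fraction=fit.explained_variance_ratio_,
    )


def exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value with midranks, by enumeration.

    Enumerates all C(n1+n2, n1) assignments of the pooled (mid)ranks to the
    first group; the p-value is the fraction of assignments whose rank sum
    deviates from its null mean by at least the observed deviation.  With
    identical value multisets in both groups the observed deviation is 0
    and p = 1.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    n1 = len(x)
    obs = ranks[:n1].sum()
    mean = ranks.sum() * n1 / len(pooled)
    obs_dev = abs(obs - mean)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        if abs(w - mean) >= obs_dev - 1e-9:
            count += 1
        total += 1
    return count / total


@dataclass
class PairwiseTestResult:
    trait_name: str
    table: pd.DataFrame  # rows: group_a, group_b, statistic, p_value, adjusted_p


def pairwise_group_tests(
    values: pd.Series,
    partition,
    adjust: str | None = "holm",
    exact_max_n: int = 10,
    trait_name: str = "",
) -> PairwiseTestResult:
    """Two-sided rank-sum tests on species-level values for every group pair.

    Uses exact enumeration with midranks when both groups have at most
    ``exact_max_n`` values, and the tie-corrected normal approximation
    (Mann-Whitney U) otherwise.  Pairs where a group has fewer than 2
    values are skipped with a warning.  Optional Holm adjustment across
    pairs.
    """
    import logging

    from .cluster import Partition

    logger = logging.getLogger(__name__)
    if isinstance(partition, Partition):
        labels = partition.labels
    else:
        labels = pd.Series(dict(partition)) if not isinstance(partition, pd.Series) else partition
    labels = labels.reindex(values.index)
    groups = {g: values[labels == g].to_numpy() for g in sorted(labels.dropna().unique())}

    rows = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        x, y = groups[ga], groups[gb]
        if len(x) < 2 or len(y) < 2:
            logger.warning("skipping pair (%s, %s): fewer than 2 values", ga, gb)
            continue
        if len(x) <= exact_max_n and len(y) <= exact_max_n:
            u = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
            p = exact_ranksum_p(x, y)
        else:
            res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            u, p = res.statistic, res.pvalue
        rows.append({"group_a": ga, "group_b": gb, "statistic": float(u), "p_value": float(p)})

    table = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p_value"])
    if adjust == "holm" and len(table):
        from statsmodels.stats.multitest import multipletests

        table["adjusted_p"] = multipletests(table["p_value"], method="holm")[1]
    else:
        table["adjusted_p"] = np.nan
    return PairwiseTestResult(trait_name=trait_name, table=table)
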