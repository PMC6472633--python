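"""Agreement between species partitions: matching, consistency, weighting.

Cluster labels are arbitrary, so comparing a clustering to the a priori
functional groups requires first finding the one-to-one label matching
that maximizes the number of co-classified species (an assignment
problem).  "Consistency" is then the proportion of species whose matched
cluster label equals their reference group, overall, per group, and
weighted by community abundance from plot-level cover data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import Partition
from .io import CoverTable, ValidationError

logger = logging.getLogger(__name__)


def confusion(a: Partition, b: Partition) -> pd.DataFrame:
    """Cross-tabulate co-assignments over the species common to both partitions.

    Rows are labels of ``a`` (the reference), columns labels of ``b``.
    """
    common = a.labels.index.intersection(b.labels.index)
    if len(common) == 0:
        raise ValidationError("partitions share no species")
    return pd.crosstab(a.labels.loc[common], b.labels.loc[common])


def optimal_matching(
    cm: pd.DataFrame, method: str = "auto", exhaustive_max: int = 8
) -> tuple[dict, int]:
    """Best one-to-one assignment of column labels to row labels.

    Maximizes the sum of matched cells.  ``method`` is ``"exhaustive"``
    (all permutations of the smaller label set, ties broken by first-found
    in lexicographic order), ``"hungarian"`` (linear-sum assignment), or
    ``"auto"`` (exhaustive when min(rows, cols) <= ``exhaustive_max``).
    Returns (mapping column label -> row label, n_consistent).
    """
    counts = cm.to_numpy()
    nr, nc = counts.shape
    if method == "auto":
        method = "exhaustive" if min(nr, nc) <= exhaustive_max else "hungarian"

    if method == "exhaustive":
        best, best_assign = -1, None
        if nr <= nc:
            # assign each row to a distinct column
            for cols in itertools.permutations(range(nc), nr):
                total = counts[np.arange(nr), cols].sum()
                if total > best:
                    best, best_assign = total, list(zip(cols, range(nr)))
        else:
            for rows in itertools.permutations(range(nr), nc):
                total = counts[rows, np.arange(nc)].sum()
                if total > best:
                    best, best_assign = total, list(zip(range(nc), rows))
    elif method == "hungarian":
        from scipy.optimize import linear_sum_assignment

        rows, cols = linear_sum_assignment(counts, maximize=True)
        best = counts[rows, cols].sum()
        best_assign = list(zip(cols, rows))
    else:
        raise ValidationError(f"unknown matching method {method!r}")

    mapping = {cm.columns[c]: cm.index[r] for c, r in best_assign}
    return mapping, int(best)


@dataclass
class ConsistencyResult:
    """Agreement of one comparison partition (or all of them) with a reference."""

    comparison: str
    matching: dict | None
    n_consistent: int
    proportion_overall: float
    proportion_per_group: dict
    consistent_species: set
    abundance_weighted_proportion: float | None = None

    def rows(self) -> list[dict]:
        out = [
            {
                "comparison": self.comparison,
                "group": "all",
                "proportion_species": self.proportion_overall,
                "proportion_abundance": self.abundance_weighted_proportion,
            }
        ]
        for g, p in self.proportion_per_group.items():
            out.append(
                {
                    "comparison": self.comparison,
                    "group": g,
                    "proportion_species": p,
                    "proportion_abundance": None,
                }
            )
        return out


def _consistent_set(reference: Partition, other: Partition, matching: dict) -> set:
    common = reference.labels.index.intersection(other.labels.index)
    mapped = other.labels.loc[common].map(matching)
    return set(common[(mapped == reference.labels.loc[common]).to_numpy()])


def _per_group(reference: Partition, consistent: set, common) -> dict:
    out = {}
    ref = reference.labels.loc[common]
    for g in sorted(ref.unique()):
        members = set(ref.index[ref == g])
        out[g] = len(members & consistent) / len(members)
    return out


def abundance_weighting(
    consistent: set,
    cover: CoverTable,
    species_with_traits: set,
    mode: str = "site_mean",
) -> float:
    """Abundance-weighted consistency from plot-level cover data.

    Per plot, the most recent year is used; cover is summed to the site
    level by species and restricted to species with trait data.  Each
    site contributes the ratio (cover of consistent species) / (cover of
    all retained species); ``mode="site_mean"`` (default) returns the
    unweighted mean over sites, ``mode="pooled"`` pools cover across all
    sites before taking the ratio.  Sites with zero retained cover are
    excluded with a warning.
    """
    rows = cover.rows
    if rows.empty:
        raise ValidationError("empty cover table")
    latest = rows.groupby(["site", "plot"])["year"].transform("max")
    rows = rows[rows["year"] == latest]
    site_cover = (
        rows.groupby(["site", "species_name"], as_index=False)["cover"].sum()
    )
    site_cover = site_cover[site_cover["species_name"].isin(species_with_traits)]

    if mode == "pooled":
        total = site_cover["cover"].sum()
        if total == 0:
            raise ValidationError("no retained cover")
        hit = site_cover[site_cover["species_name"].isin(consistent)]["cover"].sum()
        return float(hit / total)

    ratios = []
    for site, sub in site_cover.groupby("site"):
        total = sub["cover"].sum()
        if total == 0:
            logger.warning("site %r has zero retained cover; excluded", site)
            continue
        hit = sub[sub["species_name"].isin(consistent)]["cover"].sum()
        ratios.append(hit / total)
    if not ratios:
        raise ValidationError("no site with retained cover")
    return float(np.mean(ratios))


def consistency(
    reference: Partition,
    others: dict,
    cover: CoverTable | None = None,
    species_with_traits: set | None = None,
    breakdown_by: Partition | None = None,
    abundance_mode: str = "site_mean",
) -> dict:
    """Consistency of one or more comparison partitions with a reference.

    For each comparison partition its labels are matched to the reference
    by :func:`optimal_matching`; species whose matched label equals their
    reference label are "consistent".  The returned dict has one
    :class:`ConsistencyResult` per comparison plus, when there are two or
    more comparisons, an ``"all_methods"`` entry whose consistent set is
    the intersection (species consistent under *every* comparison).
    Per-group proportions are broken down by ``breakdown_by`` (default:
    the reference itself).  With ``cover`` given, abundance-weighted
    proportions are attached per :func:`abundance_weighting`.
    """
    if not others:
        raise ValidationError("need at least one comparison partition")
    breakdown = breakdown_by or reference
    common = reference.labels.index
    for p in others.values():
        common = common.intersection(p.labels.index)
    if species_with_traits is None:
        species_with_traits = set(common)

    results: dict[str, ConsistencyResult] = {}
    sets = []
    for name, other in others.items():
        cm = confusion(reference, other)
        matching, n_consistent = optimal_matching(cm)
        cset = _consistent_set(reference, other, matching)
        sets.append(cset)
        res = ConsistencyResult(
            comparison=name,
            matching=matching,
            n_consistent=len(cset & set(common)),
            proportion_overall=len(cset & set(common)) / len(common),
            proportion_per_group=_per_group(breakdown, cset, common),
            consistent_species=cset,
        )
        if cover is not None:
            res.abundance_weighted_proportion = abundance_weighting(
                cset, cover, species_with_traits, mode=abundance_mode
            )
        results[name] = res

    if len(others) >= 2:
        all_set = set.intersection(*sets) & set(common)
        res = ConsistencyResult(
            comparison="all_methods",
            matching=None,
            n_consistent=len(all_set),
            proportion_overall=len(all_set) / len(common),
            proportion_per_group=_per_group(breakdown, all_set, common),
            consistent_species=all_set,
        )
        if cover is not None:
            res.abundance_weighted_proportion = abundance_weighting(
                all_set, cover, species_with_traits, mode=abundance_mode
            )
        results["all_methods"] = res
    return results
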