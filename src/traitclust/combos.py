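"""Variance explained by a grouping for every trait subset, with resampling.

Different trait combinations have data for different numbers of species,
so raw R^2 values are not comparable across subsets.  Following the
study design this module equalizes sample size by drawing a fixed number
of species without replacement from each subset's complete-case pool and
averaging the group R^2 over many replications.  Subsets are classed as
economic-only ({SLA, LDMC, leaf N}), size-only ({plant height, seed
mass, leaf area}) or mixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GroupScheme, TraitDataset, ValidationError
from .matrix import AggregationSpec, build_matrix
from .stats import coordinate_r2

ECONOMIC_TRAITS = frozenset({"SLA", "LDMC", "leaf_N"})
SIZE_TRAITS = frozenset({"plant_height", "seed_mass", "leaf_area"})


def classify_subset(traits) -> str:
    s = set(traits)
    if s <= ECONOMIC_TRAITS:
        return "economic_only"
    if s <= SIZE_TRAITS:
        return "size_only"
    return "mixed"


def enumerate_trait_subsets(traits: list[str], min_size: int = 1) -> list[tuple]:
    """All subsets of the trait list with at least ``min_size`` members.

    Deterministic (size, lexicographic) order.
    """
    if not traits:
        raise ValidationError("no traits")
    out = []
    for size in range(max(min_size, 1), len(traits) + 1):
        out.extend(itertools.combinations(sorted(traits), size))
    return out


@dataclass
class ComboResult:
    trait_subset: tuple
    n_species_drawn: int
    n_replications: int
    r2_mean: float
    r2_sd: float
    subset_class: str
    pool_size: int
    degenerate: bool = False  # pool did not exceed the requested draw size

    def as_row(self) -> dict:
        return {
            "traits": "+".join(self.trait_subset),
            "n_traits": len(self.trait_subset),
            "n_species_drawn": self.n_species_drawn,
            "pool_size": self.pool_size,
            "n_replications": self.n_replications,
            "r2_mean": self.r2_mean,
            "r2_sd": self.r2_sd,
            "subset_class": self.subset_class,
            "degenerate": self.degenerate,
        }


def resampled_group_r2(
    ds: TraitDataset,
    subset,
    scheme: GroupScheme,
    n_species: int = 295,
    n_reps: int = 999,
    seed: int | None = None,
    aggregation: AggregationSpec | None = None,
    scaling: str = "minmax",
) -> ComboResult:
    """Mean group R^2 for one trait subset under species resampling.

    The complete-case matrix for the subset is built once (standardization
    over the full pool); each replication draws ``n_species`` species
    without replacement (the whole pool, flagged degenerate, if the pool
    is not larger) and computes the one-way group R^2 from coordinates —
    identical to PERMANOVA R^2 on Euclidean distances, with no
    permutations since only the point estimate is averaged.
    """
    subset = tuple(subset)
    m = build_matrix(ds, list(subset), aggregation=aggregation, scaling=scaling)
    in_scheme = [s for s in m.species if s in scheme.assignment.index]
    if len(in_scheme) < 3:
        raise ValidationError("fewer than 3 classified complete-case species")
    x = m.values.loc[in_scheme].to_numpy()
    codes, _ = pd.factorize(scheme.assignment.loc[in_scheme])
    if len(np.unique(codes)) < 2:
        raise ValidationError("complete-case pool spans a single group")

    pool = len(in_scheme)
    degenerate = pool <= n_species
    draw = min(n_species, pool)
    rng = np.random.default_rng(seed)
    if degenerate:
        # every replication would use the whole pool: identical by construction
        r2s = np.full(n_reps, coordinate_r2(x, codes))
    else:
        r2s = np.empty(n_reps)
        for i in range(n_reps):
            for _ in range(100):
                idx = rng.choice(pool, size=draw, replace=False)
                if len(np.unique(codes[idx])) >= 2:
                    break
            else:
                raise ValidationError("could not draw a sample spanning >= 2 groups")
            r2s[i] = coordinate_r2(x[idx], codes[idx])

    return ComboResult(
        trait_subset=subset,
        n_species_drawn=draw,
        n_replications=n_reps,
        r2_mean=float(r2s[0]) if degenerate else float(r2s.mean()),
        r2_sd=float(r2s.std(ddof=1)) if n_reps > 1 and not degenerate else 0.0,
        subset_class=classify_subset(subset),
        pool_size=pool,
        degenerate=degenerate,
    )


def run_all_combinations(
    ds: TraitDataset,
    traits: list[str],
    scheme: GroupScheme,
    n_species: int = 295,
    n_reps: int = 999,
    seed: int | None = None,
    min_size: int = 1,
    aggregation: AggregationSpec | None = None,
    scaling: str = "minmax",
) -> list[ComboResult]:
    """Resampled group R^2 for every trait subset; per-subset seeds are derived
    from ``seed`` by subset index so subsets redraw species independently."""
    subsets = enumerate_trait_subsets(traits, min_size=min_size)
    results = []
    for i, subset in enumerate(subsets):
        sub_seed = None if seed is None else int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)
        )
        results.append(
            resampled_group_r2(
                ds, subset, scheme, n_species=n_species, n_reps=n_reps,
                seed=sub_seed, aggregation=aggregation, scaling=scaling,
            )
        )
    return results


def combo_summary(results: list[ComboResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subset table plus class-level means.

    Class groupings: economic-only vs size-only vs mixed; subsets
    containing LDMC; subsets containing plant height or seed mass.
    """
    if not results:
        raise ValidationError("no combination results")
    table = pd.DataFrame([r.as_row() for r in results])
    groups = []
    for name, mask in [
        ("economic_only", table["subset_class"] == "economic_only"),
        ("size_only", table["subset_class"] == "size_only"),
        ("mixed", table["subset_class"] == "mixed"),
        ("contains_LDMC", table["traits"].str.split("+").apply(lambda t: "LDMC" in t)),
        (
            "contains_PH_or_SM",
            table["traits"].str.split("+").apply(
                lambda t: "plant_height" in t or "seed_mass" in t
            ),
        ),
    ]:
        if mask.any():
            groups.append(
                {
                    "class": name,
                    "n_subsets": int(mask.sum()),
                    "mean_r2": float(table.loc[mask, "r2_mean"].mean()),
                }
            )
    return table, pd.DataFrame(groups)
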