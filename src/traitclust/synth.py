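"""Synthetic trait databases with known (planted) group structure.

The generator emulates the statistical shape of a compiled tundra trait
database: log-normally distributed trait values, species nested in
functional groups with configurable between-group separation on the log10
scale, within-species measurement noise across repeated records,
per-trait missingness, and skewed species abundances in a plot-level
cover table.  Because the planted partition and the generating variances
are known, every downstream stage (cleaning, matrices, PERMANOVA,
clustering, consistency) can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CoverTable, GroupScheme, TraitDataset, ValidationError

#: The six core traits, in canonical order.
CORE_TRAITS = ("plant_height", "seed_mass", "leaf_area", "SLA", "LDMC", "leaf_N")

#: log10-scale group archetypes for a tundra-like 4-group community:
#: evergreen shrubs most conservative (lowest SLA and leaf N, highest
#: LDMC), forbs most acquisitive, shrubs taller with larger seeds.
#: Units: height cm, seed mass mg, leaf area mm^2, SLA mm^2/mg,
#: LDMC g/g, leaf N mg/g.
DEFAULT_GROUP_MEANS = {
    "evergreen_shrub": [1.00, 0.05, 1.90, 0.60, -0.35, 0.90],
    "deciduous_shrub": [1.25, 0.10, 2.20, 1.05, -0.65, 1.25],
    "graminoid": [1.20, -0.15, 2.00, 1.10, -0.45, 1.15],
    "forb": [1.05, -0.30, 2.15, 1.30, -0.85, 1.40],
}

DEFAULT_UNITS = {
    "plant_height": "cm",
    "seed_mass": "mg",
    "leaf_area": "mm2",
    "SLA": "mm2/mg",
    "LDMC": "g/g",
    "leaf_N": "mg/g",
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic trait database.

    Trait values for species s in group g are generated as
    log10(value) = group_mean[g, t] + species offset + record noise, with
    species offsets ~ N(0, trait_sd_between_species[t]) and record noise
    ~ N(0, within_species_sd[t]).  Cover per (site, plot, year) is a
    symmetric Dirichlet draw over species scaled to 100 (percent cover);
    small ``abundance_shape`` concentrations give realistically skewed
    rank-abundance curves.
    """

    n_groups: int = 4
    species_per_group: int = 100  # 400 species; ~295 complete cases for 6 traits
    traits: tuple = CORE_TRAITS
    group_means: dict | None = None  # group -> list of log10 means per trait
    trait_sd_between_species: dict | float = 0.4
    within_species_sd: dict | float = 0.12
    records_per_species: tuple = (3, 12)  # inclusive range, uniform
    missing_fraction: dict | float = 0.05
    n_sites: int = 5
    plots_per_site: int = 8
    years: tuple = (2010, 2012, 2015)
    abundance_shape: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.group_means is None:
            names = list(DEFAULT_GROUP_MEANS)
            if self.n_groups <= len(names):
                self.group_means = {
                    g: list(DEFAULT_GROUP_MEANS[g]) for g in names[: self.n_groups]
                }
            else:
                raise ValidationError(
                    "group_means must be given explicitly for n_groups > 4"
                )
        if len(self.group_means) != self.n_groups:
            raise ValidationError("group_means size does not match n_groups")
        for g, mu in self.group_means.items():
            if len(mu) != len(self.traits):
                raise ValidationError(f"group {g!r} means do not match traits")
        for t, v in self._per_trait(self.missing_fraction).items():
            if not (0 <= v < 1):
                raise ValidationError(f"missing_fraction[{t}] must be in [0, 1)")
        for attr in ("trait_sd_between_species", "within_species_sd"):
            for t, v in self._per_trait(getattr(self, attr)).items():
                if v < 0:
                    raise ValidationError(f"{attr}[{t}] must be >= 0")

    def _per_trait(self, value) -> dict:
        if isinstance(value, dict):
            return {t: float(value.get(t, 0.0)) for t in self.traits}
        return {t: float(value) for t in self.traits}

    @property
    def n_species(self) -> int:
        return self.n_groups * self.species_per_group

    @property
    def mean_records(self) -> float:
        lo, hi = self.records_per_species
        return (lo + hi) / 2.0

    @property
    def mean_inverse_records(self) -> float:
        lo, hi = self.records_per_species
        return float(np.mean([1.0 / m for m in range(lo, hi + 1)]))


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a synthetic dataset."""

    partition: GroupScheme
    species_log_means: pd.DataFrame  # species x trait, log10 scale
    config: SyntheticConfig = field(repr=False, default=None)


def generate_dataset(
    cfg: SyntheticConfig,
) -> tuple[TraitDataset, GroupScheme, CoverTable, SyntheticTruth]:
    """Draw a full synthetic study: trait records, group scheme, cover table.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(cfg.group_means)
    sd_between = cfg._per_trait(cfg.trait_sd_between_species)
    sd_within = cfg._per_trait(cfg.within_species_sd)
    miss = cfg._per_trait(cfg.missing_fraction)

    species, labels = [], []
    for gi, g in enumerate(groups):
        for si in range(cfg.species_per_group):
            species.append(f"species_{gi}_{si:03d}")
            labels.append(g)
    scheme = GroupScheme(
        scheme_name="planted",
        assignment=pd.Series(labels, index=pd.Index(species, name="species_name")),
    )

    mu = np.array([cfg.group_means[g] for g in labels], dtype=float)
    offsets = rng.normal(
        0.0, [sd_between[t] for t in cfg.traits], size=(cfg.n_species, len(cfg.traits))
    )
    species_means = mu + offsets
    truth_means = pd.DataFrame(species_means, index=species, columns=list(cfg.traits))

    lo, hi = cfg.records_per_species
    sites = [f"site_{i}" for i in range(cfg.n_sites)]
    rows = []
    for i, sp in enumerate(species):
        m = int(rng.integers(lo, hi + 1))
        for ti, t in enumerate(cfg.traits):
            if miss[t] > 0 and rng.random() < miss[t]:
                continue
            vals = species_means[i, ti] + rng.normal(0.0, sd_within[t], size=m)
            for v in vals:
                rows.append(
                    {
                        "species_name": sp,
                        "trait_name": t,
                        "value": 10.0**v,
                        "unit": DEFAULT_UNITS.get(t, "unit"),
                        "latitude": float(rng.uniform(55.0, 80.0)),
                        "longitude": float(rng.uniform(-160.0, 40.0)),
                        "site": sites[int(rng.integers(cfg.n_sites))],
                        "year": int(rng.choice(cfg.years)),
                        "source_id": f"src_{int(rng.integers(20)):02d}",
                    }
                )
    ds = TraitDataset(records=pd.DataFrame(rows))

    cover_rows = []
    for site in sites:
        for plot in range(cfg.plots_per_site):
            for year in cfg.years:
                weights = rng.dirichlet(np.full(cfg.n_species, cfg.abundance_shape))
                cover = 100.0 * weights
                keep = cover > 0.01  # trace species absent from the plot record
                for sp, c in zip(np.array(species)[keep], cover[keep]):
                    cover_rows.append(
                        {
                            "site": site,
                            "plot": f"plot_{plot}",
                            "year": int(year),
                            "species_name": sp,
                            "cover": float(c),
                        }
                    )
    cover = CoverTable(rows=pd.DataFrame(cover_rows))

    truth = SyntheticTruth(partition=scheme, species_log_means=truth_means, config=cfg)
    return ds, scheme, cover, truth


def expected_separation_r2(cfg: SyntheticConfig) -> float:
    """Large-sample group R^2 implied by the config, on the unscaled log matrix.

    Per trait the between-group variance is the population variance of the
    group means; the denominator adds the between-species variance and the
    within-species variance attenuated by the expected number of records
    per species (species-level aggregation averages record noise).  The
    value is approximate under [0, 1] rescaling, which reweights traits.
    """
    sd_between = cfg._per_trait(cfg.trait_sd_between_species)
    sd_within = cfg._per_trait(cfg.within_species_sd)
    mu = np.array(list(cfg.group_means.values()), dtype=float)  # group x trait
    vb = mu.var(axis=0, ddof=0)
    num, den = 0.0, 0.0
    for ti, t in enumerate(cfg.traits):
        vw = sd_within[t] ** 2 * cfg.mean_inverse_records
        num += vb[ti]
        den += vb[ti] + sd_between[t] ** 2 + vw
    return float(num / den) if den > 0 else 0.0


def write_synthetic_inputs(cfg: SyntheticConfig, outdir) -> dict:
    """Generate a dataset and write the CSV files the readers consume.

    Returns the file paths (trait records, group scheme, cover table,
    true species means).
    """
    import os

    ds, scheme, cover, truth = generate_dataset(cfg)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "traits": os.path.join(outdir, "trait_records.csv"),
        "groups": os.path.join(outdir, "group_scheme.csv"),
        "cover": os.path.join(outdir, "cover.csv"),
        "truth": os.path.join(outdir, "true_species_means.csv"),
    }
    ds.records.to_csv(paths["traits"], index=False)
    scheme.assignment.rename(scheme.scheme_name).rename_axis("species_name").reset_index().to_csv(
        paths["groups"], index=False
    )
    cover.rows.to_csv(paths["cover"], index=False)
    truth.species_log_means.rename_axis("species_name").to_csv(paths["truth"])
    return paths
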