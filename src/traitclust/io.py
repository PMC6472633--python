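"""Reading, validation, cleaning and subsetting of long-format trait data.

The central object is :class:`TraitDataset`, a thin wrapper around a pandas
DataFrame of individual trait measurements (one row per record) plus a
provenance report that itemizes every record removed or flagged during
cleaning.  Cleaning follows the conventions of large compiled trait
databases: exact-duplicate collapse, removal of non-positive values, a
per-species standard-deviation filter on the log scale, and a
flag-for-review rule for seed mass, which is especially error-prone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical long-format columns for trait record tables.
TRAIT_COLUMNS = [
    "species_name",
    "trait_name",
    "value",
    "unit",
    "latitude",
    "longitude",
    "site",
    "year",
    "source_id",
]

REQUIRED_TRAIT_COLUMNS = ["species_name", "trait_name", "value"]

#: Default trait vocabulary.  Six core traits plus the two rarely measured
#: ones (stem density, leaf lifespan).
DEFAULT_VOCABULARY = (
    "plant_height",
    "seed_mass",
    "leaf_area",
    "SLA",
    "LDMC",
    "leaf_N",
    "stem_density",
    "leaf_lifespan",
)

COVER_COLUMNS = ["site", "plot", "year", "species_name", "cover"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ProvenanceReport:
    """Counts of records removed per cleaning rule, plus itemized rows.

    ``counts`` maps rule name -> number of records affected.  ``removed``
    holds the removed records themselves (with a ``rule`` column);
    ``flagged`` holds records kept but marked for manual review.
    """

    counts: dict = field(default_factory=dict)
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)
    flagged: pd.DataFrame = field(default_factory=pd.DataFrame)

    def add(self, rule: str, rows: pd.DataFrame) -> None:
        self.counts[rule] = self.counts.get(rule, 0) + len(rows)
        if len(rows):
            rows = rows.assign(rule=rule)
            self.removed = pd.concat([self.removed, rows], ignore_index=True)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def summary(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_removed": int(self.n_removed),
            "n_flagged": int(len(self.flagged)),
        }


@dataclass
class TraitDataset:
    """An ordered collection of trait records with cleaning provenance."""

    records: pd.DataFrame
    provenance: ProvenanceReport = field(default_factory=ProvenanceReport)

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.records.columns]
        for c in missing:
            self.records[c] = np.nan
        self.records = self.records[TRAIT_COLUMNS].reset_index(drop=True)
        lat = self.records["latitude"].dropna()
        if len(lat) and ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_name"].unique())

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait_name"].unique())


@dataclass
class GroupScheme:
    """An a priori species -> functional-group classification.

    Standard schemes: the traditional four groups (evergreen shrubs,
    deciduous shrubs, graminoids, forbs), a six-group scheme splitting
    graminoids into grasses/sedges/rushes, and a seven-group scheme further
    splitting shrubs by stature.
    """

    scheme_name: str
    assignment: pd.Series  # index species_name -> group label

    def __post_init__(self) -> None:
        if self.assignment.index.has_duplicates:
            dup = self.assignment.index[self.assignment.index.duplicated()]
            raise ValidationError(
                f"species with multiple labels in scheme {self.scheme_name!r}: "
                f"{sorted(set(dup))}"
            )

    @property
    def k(self) -> int:
        return self.assignment.nunique()

    def to_partition(self):
        from .cluster import Partition

        return Partition(labels=self.assignment.copy(), method="a_priori")


@dataclass
class CoverTable:
    """Plot-level vegetation cover: rows of (site, plot, year, species, cover)."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COVER_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValidationError(f"cover table missing columns: {missing}")
        self.rows = self.rows[COVER_COLUMNS].reset_index(drop=True)
        if (self.rows["cover"] < 0).any():
            raise ValidationError("negative cover values")
        key = ["site", "plot", "year", "species_name"]
        if self.rows.duplicated(subset=key).any():
            raise ValidationError("duplicate (site, plot, year, species) rows")


def read_trait_records(
    path,
    column_map: dict | None = None,
    vocabulary: tuple = DEFAULT_VOCABULARY,
) -> TraitDataset:
    """Read a long-format trait CSV into a :class:`TraitDataset`.

    ``column_map`` maps file header names to canonical names (e.g.
    ``{"SpeciesName": "species_name"}``).  Rows whose value does not parse
    as a number, and rows with trait names outside ``vocabulary``, are
    reported and skipped rather than fatal.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if df.empty:
        logger.warning("empty trait file: %s", path)
        return TraitDataset(records=df)

    report = ProvenanceReport()
    df = df.assign(value=pd.to_numeric(df["value"], errors="coerce"))
    bad = ~np.isfinite(df["value"])
    if bad.any():
        logger.warning("%d rows with unparsable/non-finite value skipped", bad.sum())
        report.add("unparsable_value", df[bad])
        df = df[~bad]
    if vocabulary is not None:
        unknown = ~df["trait_name"].isin(vocabulary)
        if unknown.any():
            logger.warning(
                "%d rows with trait names outside vocabulary skipped: %s",
                unknown.sum(),
                sorted(df.loc[unknown, "trait_name"].unique()),
            )
            report.add("unknown_trait", df[unknown])
            df = df[~unknown]
    return TraitDataset(records=df, provenance=report)


def read_synonym_table(path) -> dict:
    """Read a two-column synonym CSV (synonym, accepted) into a dict.

    Accepted names must not themselves appear as synonyms (no chains).
    """
    df = pd.read_csv(path)
    for c in ("synonym", "accepted"):
        if c not in df.columns:
            raise ValidationError(f"synonym table missing column {c!r}")
    syn = dict(zip(df["synonym"], df["accepted"]))
    chained = set(syn.values()) & set(syn.keys())
    if chained:
        raise ValidationError(f"synonym chains detected via: {sorted(chained)}")
    return syn


def apply_synonyms(ds: TraitDataset, synonyms: dict) -> TraitDataset:
    """Replace synonym species names by their accepted names.

    Unknown names pass through unchanged.  The number of renamed records is
    recorded in the provenance counts under ``synonyms_renamed``.
    """
    records = ds.records.copy()
    hit = records["species_name"].isin(synonyms.keys())
    records.loc[hit, "species_name"] = records.loc[hit, "species_name"].map(synonyms)
    report = ProvenanceReport(
        counts=dict(ds.provenance.counts),
        removed=ds.provenance.removed,
        flagged=ds.provenance.flagged,
    )
    report.counts["synonyms_renamed"] = int(hit.sum())
    logger.info("renamed %d records via synonym table", hit.sum())
    return TraitDataset(records=records, provenance=report)


@dataclass
class CleaningRules:
    """Tunable thresholds for :func:`clean_dataset`."""

    sd_threshold: float = 4.0  # per species x trait, on log10 scale
    seed_mass_sd_threshold: float = 3.0  # flag only, not removal
    seed_mass_trait: str = "seed_mass"
    min_n: int = 3  # SD filter skipped below this sample size
    log_base: float = 10.0


def clean_dataset(ds: TraitDataset, rules: CleaningRules | None = None) -> TraitDataset:
    """Clean a trait dataset, itemizing every removal in the provenance.

    Rules, in order: (1) exact duplicates (species, trait, value, unit,
    source) collapsed to one record; (2) values <= 0 removed as erroneous;
    (3) per species x trait, records whose log10 value lies more than
    ``sd_threshold`` sample SDs from that species-trait mean removed
    (single pass, the point included in its own mean/SD; skipped when
    n < ``min_n`` or SD is zero); (4) seed-mass records beyond
    ``seed_mass_sd_threshold`` SDs flagged for manual review, never
    silently dropped.
    """
    rules = rules or CleaningRules()
    report = ProvenanceReport(counts=dict(ds.provenance.counts))
    df = ds.records.copy()

    dup_key = ["species_name", "trait_name", "value", "unit", "source_id"]
    dup = df.duplicated(subset=dup_key, keep="first")
    report.add("duplicate", df[dup])
    df = df[~dup]

    nonpos = df["value"] <= 0
    report.add("nonpositive_value", df[nonpos])
    df = df[~nonpos]

    logv = np.log(df["value"]) / np.log(rules.log_base)
    grp = logv.groupby([df["species_name"], df["trait_name"]])
    mean = grp.transform("mean")
    sd = grp.transform("std")  # sample SD, ddof=1
    n = grp.transform("size")
    with np.errstate(invalid="ignore"):
        z = (logv - mean).abs() / sd
    outlier = (n >= rules.min_n) & (sd > 0) & (z > rules.sd_threshold)
    report.add("sd_outlier", df[outlier])
    df = df[~outlier]

    # Seed mass: values beyond the (stricter) threshold are flagged for
    # manual review on the cleaned data, not removed.
    sm = df[df["trait_name"] == rules.seed_mass_trait]
    if len(sm):
        logv = np.log(sm["value"]) / np.log(rules.log_base)
        g = logv.groupby(sm["species_name"])
        mean, sd, n = g.transform("mean"), g.transform("std"), g.transform("size")
        with np.errstate(invalid="ignore"):
            z = (logv - mean).abs() / sd
        flag = (n >= rules.min_n) & (sd > 0) & (z > rules.seed_mass_sd_threshold)
        report.flagged = sm[flag].assign(rule="seed_mass_review")
        report.counts["seed_mass_flagged"] = int(flag.sum())

    return TraitDataset(records=df.reset_index(drop=True), provenance=report)


def subset_dataset(
    ds: TraitDataset,
    min_latitude: float | None = None,
    sites: list | None = None,
    species: list | None = None,
) -> TraitDataset:
    """Restrict a dataset by latitude, site list and/or species list.

    ``min_latitude`` keeps only georeferenced records at or above the given
    latitude (records without coordinates are dropped, matching analyses
    restricted to e.g. north of 60 degrees N).
    """
    df = ds.records
    if min_latitude is not None:
        df = df[df["latitude"].notna() & (df["latitude"] >= min_latitude)]
    if sites is not None:
        sites = [sites] if isinstance(sites, str) else list(sites)
        df = df[df["site"].isin(sites)]
    if species is not None:
        df = df[df["species_name"].isin(species)]
    if df.empty:
        logger.warning("subset filter matched no records")
    return TraitDataset(records=df.reset_index(drop=True), provenance=ds.provenance)


def read_cover_table(path) -> CoverTable:
    """Read and validate a plot-level cover CSV (site, plot, year, species, cover)."""
    return CoverTable(rows=pd.read_csv(path))


def read_group_scheme(path, scheme_name: str) -> GroupScheme:
    """Read a group classification CSV with a species column plus one column per scheme."""
    df = pd.read_csv(path)
    if "species_name" not in df.columns:
        raise ValidationError("group scheme table needs a species_name column")
    if scheme_name not in df.columns:
        raise ValidationError(f"no column {scheme_name!r} in group scheme table")
    sub = df[["species_name", scheme_name]].drop_duplicates()
    if sub["species_name"].duplicated().any():
        dups = sub.loc[sub["species_name"].duplicated(), "species_name"]
        raise ValidationError(
            f"conflicting labels for species in scheme {scheme_name!r}: {sorted(set(dups))}"
        )
    assignment = sub.set_index("species_name")[scheme_name]
    return GroupScheme(scheme_name=scheme_name, assignment=assignment)
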