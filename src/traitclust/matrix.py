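"""Species x trait matrices: log-transform, aggregate, standardize.

Traits such as plant height, seed mass and leaf area span orders of
magnitude and are approximately log-normal, so all aggregation happens on
the log10 scale.  Each trait column is then standardized across species so
that traits measured in different units contribute comparably to Euclidean
distances.  Only complete cases (species with data for every requested
trait) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TraitDataset, ValidationError


@dataclass(frozen=True)
class AggregationSpec:
    """How to collapse multiple records per species x trait to one value.

    ``statistic`` is ``"mean"`` or ``"quantile"``; for quantiles, ``q`` in
    (0, 1) selects the order statistic (linear interpolation at index
    (n-1)q).  The 25th/75th-percentile variants probe robustness to
    within-species variation.
    """

    statistic: str = "mean"
    q: float | None = None

    def __post_init__(self):
        if self.statistic not in ("mean", "quantile"):
            raise ValidationError(f"unknown statistic {self.statistic!r}")
        if self.statistic == "quantile":
            if self.q is None or not (0 < self.q < 1):
                raise ValidationError("quantile aggregation needs q in (0, 1)")
        elif self.q is not None:
            raise ValidationError("q only valid with statistic='quantile'")


@dataclass
class TraitMatrix:
    """Standardized species x trait table plus the metadata to invert it.

    ``values`` holds one row per species and one column per trait, scaled
    per trait.  ``scaling`` maps trait -> dict with the log base and the
    affine transform applied, so aggregated log values are recoverable.
    """

    values: pd.DataFrame
    scaling: dict
    aggregation: AggregationSpec = field(default_factory=AggregationSpec)
    scaling_mode: str = "minmax"

    @property
    def species(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def inverse_transform(self) -> pd.DataFrame:
        """Recover the aggregated log-scale values from the scaled matrix."""
        out = {}
        for t in self.traits:
            meta = self.scaling[t]
            out[t] = self.values[t] * meta["scale"] + meta["location"]
        return pd.DataFrame(out, index=self.values.index)


def _aggregate(logv: pd.Series, spec: AggregationSpec) -> float:
    if spec.statistic == "mean":
        return logv.mean()
    return np.quantile(logv.to_numpy(), spec.q)  # linear interpolation


def build_matrix(
    ds: TraitDataset,
    traits: list[str],
    aggregation: AggregationSpec | None = None,
    scaling: str = "minmax",
    log_base: float = 10.0,
    min_species: int = 3,
) -> TraitMatrix:
    """Build a standardized species x trait matrix from cleaned records.

    Pipeline order: log-transform each record value, aggregate per species
    x trait (statistic over log values), restrict to complete cases, then
    scale each trait column across species.

    Scaling modes: ``"minmax"`` maps each trait to [0, 1] (default);
    ``"zscore"`` centers to mean 0, SD 1 (values not confined to [0, 1]).
    Either way the transform is affine per trait and recorded in
    ``scaling`` as ``location``/``scale`` with ``scaled = (log - location)
    / scale``.
    """
    aggregation = aggregation or AggregationSpec()
    if not traits:
        raise ValidationError("no traits requested")
    df = ds.records[ds.records["trait_name"].isin(traits)]
    missing = set(traits) - set(df["trait_name"].unique())
    if missing:
        raise ValidationError(f"no records for requested traits: {sorted(missing)}")

    logv = np.log(df["value"]) / np.log(log_base)
    agg = (
        logv.groupby([df["species_name"], df["trait_name"]])
        .apply(lambda s: _aggregate(s, aggregation))
        .unstack("trait_name")
        .reindex(columns=traits)
    )
    agg = agg.dropna(axis=0, how="any")  # complete cases only
    if len(agg) < min_species:
        raise ValidationError(
            f"only {len(agg)} complete-case species for traits {traits}; "
            f"need at least {min_species}"
        )
    agg = agg.sort_index()

    meta = {}
    scaled = {}
    for t in traits:
        col = agg[t]
        if scaling == "minmax":
            lo, hi = col.min(), col.max()
            scale = hi - lo if hi > lo else 1.0
            location = lo
        elif scaling == "zscore":
            location = col.mean()
            sd = col.std(ddof=1)
            scale = sd if sd > 0 else 1.0
        else:
            raise ValidationError(f"unknown scaling mode {scaling!r}")
        scaled[t] = (col - location) / scale
        meta[t] = {"log_base": log_base, "location": float(location), "scale": float(scale)}

    return TraitMatrix(
        values=pd.DataFrame(scaled, index=agg.index)[traits],
        scaling=meta,
        aggregation=aggregation,
        scaling_mode=scaling,
    )


def matrix_subset(m: TraitMatrix, traits: list[str]) -> TraitMatrix:
    """Restrict a matrix to a subset of its trait columns.

    Species stay as built (the matrix is complete-case already); column
    scaling is *not* redone, so subset distances live in the same scaled
    space as the full matrix.
    """
    if not traits:
        raise ValidationError("empty trait subset")
    unknown = set(traits) - set(m.traits)
    if unknown:
        raise ValidationError(f"traits not in matrix: {sorted(unknown)}")
    return TraitMatrix(
        values=m.values[list(traits)].copy(),
        scaling={t: m.scaling[t] for t in traits},
        aggregation=m.aggregation,
        scaling_mode=m.scaling_mode,
    )


def write_matrix(m: TraitMatrix, csv_path, meta_path=None) -> None:
    """Serialize a matrix as CSV plus an optional JSON sidecar with scaling metadata."""
    import json

    m.values.rename_axis("species_name").to_csv(csv_path)
    if meta_path is not None:
        meta = {
            "scaling_mode": m.scaling_mode,
            "scaling": m.scaling,
            "aggregation": {"statistic": m.aggregation.statistic, "q": m.aggregation.q},
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)


def read_matrix(csv_path, meta_path) -> TraitMatrix:
    import json

    values = pd.read_csv(csv_path, index_col="species_name")
    with open(meta_path) as fh:
        meta = json.load(fh)
    agg = AggregationSpec(**meta["aggregation"])
    return TraitMatrix(
        values=values,
        scaling=meta["scaling"],
        aggregation=agg,
        scaling_mode=meta["scaling_mode"],
    )
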