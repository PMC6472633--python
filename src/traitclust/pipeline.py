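"""End-to-end orchestration of the functional-group evaluation workflow.

A single :class:`AnalysisConfig` (usually loaded from YAML) drives the
whole study: clean the trait records, build the standardized species x
trait matrix, test each a priori grouping scheme with PERMANOVA (overall
and for economic-only / size-only trait subsets), run PCA and per-trait
pairwise rank tests, cluster species post hoc with k-means and Ward at
each scheme's k, score partition agreement with and without abundance
weighting, and sweep every trait combination with species resampling.
All randomness flows through seeded generators; the global seed is
expanded into independent per-stage seeds so stages are reproducible in
isolation.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import combos as _combos
from . import correspondence as _corr
from . import io as _io
from . import matrix as _matrix
from . import stats as _stats
from . import synth as _synth

logger = logging.getLogger(__name__)

STAGE_IDS = {
    "simulate": 0,
    "permanova": 1,
    "kmeans": 2,
    "combos": 3,
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent, reproducible sub-seed for a pipeline stage."""
    idx = STAGE_IDS[stage]
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % (2**31))


@dataclass
class AnalysisConfig:
    """Run-level settings for :func:`run_full_analysis`.

    Either ``synthetic`` (a :class:`~traitclust.synth.SyntheticConfig` or
    kwargs dict) or explicit input ``paths`` must be provided.  Study-style
    defaults: 999 permutations, 999 resampling replications, 295 species
    per draw.
    """

    synthetic: dict | _synth.SyntheticConfig | None = None
    paths: dict = field(default_factory=dict)  # traits/groups/cover/synonyms CSVs
    traits: tuple = _synth.CORE_TRAITS
    scheme_names: tuple = ("planted",)
    aggregation: _matrix.AggregationSpec = field(default_factory=_matrix.AggregationSpec)
    scaling: str = "minmax"
    n_permutations: int = 999
    kmeans_n_init: int = 100
    combos_n_species: int = 295
    combos_n_reps: int = 999
    combos_min_size: int = 1
    run_combos: bool = True
    min_latitude: float | None = None
    sites: list | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "aggregation" in d and isinstance(d["aggregation"], dict):
            d["aggregation"] = _matrix.AggregationSpec(**d["aggregation"])
        for key in ("traits", "scheme_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _load_inputs(cfg: AnalysisConfig, outdir=None):
    """Resolve inputs: generate synthetic data or read the configured files."""
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        if isinstance(syn, dict):
            syn = dict(syn)
            syn.setdefault("seed", stage_seed(cfg.seed, "simulate"))
            syn = _synth.SyntheticConfig(**syn)
        ds, scheme, cover, truth = _synth.generate_dataset(syn)
        return ds, {scheme.scheme_name: scheme}, cover
    if not cfg.paths.get("traits"):
        raise _io.ValidationError("config needs either 'synthetic' or paths['traits']")
    ds = _io.read_trait_records(cfg.paths["traits"])
    if cfg.paths.get("synonyms"):
        ds = _io.apply_synonyms(ds, _io.read_synonym_table(cfg.paths["synonyms"]))
    schemes = {}
    if cfg.paths.get("groups"):
        for name in cfg.scheme_names:
            schemes[name] = _io.read_group_scheme(cfg.paths["groups"], name)
    cover = _io.read_cover_table(cfg.paths["cover"]) if cfg.paths.get("cover") else None
    return ds, schemes, cover


def _permanova_row(result, analysis, trait_class, n_species, variant="base"):
    row = result.as_dict()
    row.update(
        analysis=analysis, trait_class=trait_class, n_species=n_species, variant=variant
    )
    return row


def run_full_analysis(cfg: AnalysisConfig, outdir) -> dict:
    """Execute the full workflow and write all result tables to ``outdir``.

    Returns the JSON-ready summary dict (also written to summary.json).
    Any stage failure aborts with a stage-tagged message; tables written
    before the failure are retained.
    """
    os.makedirs(outdir, exist_ok=True)
    stage = "load"
    try:
        ds, schemes, cover = _load_inputs(cfg, outdir)
        if cfg.min_latitude is not None or cfg.sites is not None:
            ds = _io.subset_dataset(ds, min_latitude=cfg.min_latitude, sites=cfg.sites)

        stage = "clean"
        ds = _io.clean_dataset(ds)
        ds.records.to_csv(os.path.join(outdir, "records_clean.csv"), index=False)
        with open(os.path.join(outdir, "cleaning_report.json"), "w") as fh:
            json.dump(ds.provenance.summary(), fh, indent=2, sort_keys=True)

        stage = "matrix"
        m = _matrix.build_matrix(
            ds, list(cfg.traits), aggregation=cfg.aggregation, scaling=cfg.scaling
        )
        _matrix.write_matrix(
            m, os.path.join(outdir, "matrix.csv"), os.path.join(outdir, "matrix_meta.json")
        )
        dm = _stats.euclidean_distances(m)

        stage = "pca"
        pca_res = _stats.pca(m)
        pca_res.scores.rename_axis("species_name").to_csv(os.path.join(outdir, "pca_scores.csv"))
        pca_res.loadings.rename_axis("trait_name").to_csv(os.path.join(outdir, "pca_loadings.csv"))

        stage = "pairwise_tests"
        agg_log = m.inverse_transform()
        primary_scheme = schemes[cfg.scheme_names[0]] if schemes else None
        pairwise_rows = []
        if primary_scheme is not None:
            part = primary_scheme.to_partition()
            for t in cfg.traits:
                res = _stats.pairwise_group_tests(agg_log[t], part, trait_name=t)
                tab = res.table.assign(trait_name=t)
                pairwise_rows.append(tab)
            pd.concat(pairwise_rows, ignore_index=True).to_csv(
                os.path.join(outdir, "pairwise_tests.csv"), index=False
            )

        stage = "permanova"
        perm_seed = stage_seed(cfg.seed, "permanova")
        km_seed = stage_seed(cfg.seed, "kmeans")
        econ = [t for t in cfg.traits if t in _combos.ECONOMIC_TRAITS]
        size = [t for t in cfg.traits if t in _combos.SIZE_TRAITS]
        perm_rows = []
        partitions = {}
        consistency_rows = []
        summary: dict = {"n_species": len(m.species), "traits": list(cfg.traits)}

        for name, scheme in schemes.items():
            ref = scheme.to_partition()
            common = [s for s in m.species if s in ref.labels.index]
            sub_m = _matrix.TraitMatrix(
                values=m.values.loc[common], scaling=m.scaling,
                aggregation=m.aggregation, scaling_mode=m.scaling_mode,
            )
            sub_dm = _stats.euclidean_distances(sub_m)
            res = _stats.permanova(sub_dm, ref, cfg.n_permutations, seed=perm_seed)
            perm_rows.append(_permanova_row(res, f"scheme:{name}", "all", len(common)))
            summary[f"r2_{name}"] = res.r_squared
            summary[f"p_{name}"] = res.p_value

            stage = "clustering"
            k = scheme.k
            km = _cluster.kmeans_cluster(sub_m, k, n_init=cfg.kmeans_n_init, seed=km_seed)
            tree = _cluster.ward_linkage(sub_m)
            hca = _cluster.cut_tree(tree, k)
            partitions[f"{name}"] = ref
            partitions[f"kmeans_k{k}"] = km.partition
            partitions[f"hca_k{k}"] = hca
            if name == cfg.scheme_names[0]:
                tree.to_frame().to_csv(os.path.join(outdir, "linkage.csv"), index=False)

            for pname, part in [("kmeans", km.partition), ("hca", hca)]:
                res_p = _stats.permanova(sub_dm, part, cfg.n_permutations, seed=perm_seed)
                perm_rows.append(
                    _permanova_row(res_p, f"{pname}_k{k}", "all", len(common))
                )
                summary[f"r2_{pname}_k{k}"] = res_p.r_squared

            for cls_name, cls_traits in [("economic_only", econ), ("size_only", size)]:
                if not cls_traits:
                    continue
                cls_m = _matrix.matrix_subset(sub_m, cls_traits)
                cls_dm = _stats.euclidean_distances(cls_m)
                for pname, part in [
                    (f"scheme:{name}", ref),
                    (f"kmeans_k{k}", km.partition),
                    (f"hca_k{k}", hca),
                ]:
                    res_c = _stats.permanova(cls_dm, part, cfg.n_permutations, seed=perm_seed)
                    perm_rows.append(
                        _permanova_row(res_c, pname, cls_name, len(common))
                    )

            stage = "consistency"
            cons = _corr.consistency(
                ref,
                {"kmeans": km.partition, "hca": hca},
                cover=cover,
                species_with_traits=set(common),
            )
            pair = _corr.consistency(
                km.partition, {"hca": hca}, cover=cover,
                species_with_traits=set(common), breakdown_by=ref,
            )["hca"]
            pair.comparison = "kmeans_vs_hca"
            for res_c in list(cons.values()) + [pair]:
                for row in res_c.rows():
                    row["scheme"] = name
                    consistency_rows.append(row)
            if name == cfg.scheme_names[0]:
                for key, res_c in [
                    ("kmeans", cons["kmeans"]), ("hca", cons["hca"]),
                    ("all_methods", cons["all_methods"]), ("kmeans_vs_hca", pair),
                ]:
                    summary[f"consistency_{key}_pct"] = 100 * res_c.proportion_overall
                    if res_c.abundance_weighted_proportion is not None:
                        summary[f"consistency_{key}_abundance_pct"] = (
                            100 * res_c.abundance_weighted_proportion
                        )

        pd.DataFrame(perm_rows).to_csv(
            os.path.join(outdir, "permanova_results.csv"), index=False
        )
        parts_df = pd.DataFrame(
            {name: p.labels for name, p in partitions.items()}
        ).rename_axis("species_name")
        parts_df.to_csv(os.path.join(outdir, "partitions.csv"))
        pd.DataFrame(consistency_rows).to_csv(
            os.path.join(outdir, "consistency.csv"), index=False
        )

        stage = "combos"
        if cfg.run_combos and primary_scheme is not None:
            combo_results = _combos.run_all_combinations(
                ds, list(cfg.traits), primary_scheme,
                n_species=cfg.combos_n_species, n_reps=cfg.combos_n_reps,
                seed=stage_seed(cfg.seed, "combos"), min_size=cfg.combos_min_size,
                aggregation=cfg.aggregation, scaling=cfg.scaling,
            )
            table, classes = _combos.combo_summary(combo_results)
            table.to_csv(os.path.join(outdir, "combos.csv"), index=False)
            classes.to_csv(os.path.join(outdir, "combo_classes.csv"), index=False)
            for _, row in classes.iterrows():
                summary[f"combo_mean_r2_{row['class']}"] = row["mean_r2"]

        summary["seed"] = cfg.seed
        with open(os.path.join(outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
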