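import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from traitclust import (
    SyntheticConfig,
    build_matrix,
    clean_dataset,
    coordinate_r2,
    cut_tree,
    expected_separation_r2,
    generate_dataset,
    kmeans_cluster,
    ward_linkage,
)
from traitclust.io import ValidationError


def _null_config(**kw):
    """All groups share the same trait means: no planted signal."""
    means = {f"g{i}": [1.0, 0.0, 2.0, 1.0, -0.5, 1.2] for i in range(4)}
    defaults = dict(
        species_per_group=20,
        group_means=means,
        trait_sd_between_species=0.3,
        within_species_sd=0.0,
        missing_fraction=0.0,
        records_per_species=(1, 1),
        n_sites=1,
        plots_per_site=1,
        seed=0,
    )
    defaults.update(kw)
    return SyntheticConfig(**defaults)


class TestGenerateDataset:
    def test_reproducible_from_seed(self):
        cfg = SyntheticConfig(species_per_group=6, seed=9)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        pd.testing.assert_frame_equal(a[0].records, b[0].records)
        pd.testing.assert_frame_equal(a[2].rows, b[2].rows)

    def test_zero_noise_collapses_groups_to_points(self):
        cfg = SyntheticConfig(
            species_per_group=6,
            trait_sd_between_species=0.0,
            within_species_sd=0.0,
            missing_fraction=0.0,
            records_per_species=(1, 1),
            n_sites=1,
            plots_per_site=1,
            seed=1,
        )
        ds, scheme, _, truth = generate_dataset(cfg)
        m = build_matrix(ds, list(cfg.traits))
        codes, _ = pd.factorize(scheme.assignment.loc[m.species])
        # all species in a group identical -> between-group R^2 = 1
        assert coordinate_r2(m.to_numpy(), codes) == pytest.approx(1.0)
        km = kmeans_cluster(m, 4, n_init=10, seed=0)
        hca = cut_tree(ward_linkage(m), 4)
        assert adjusted_rand_score(codes, km.partition.labels.to_numpy()) == 1.0
        assert adjusted_rand_score(codes, hca.labels.to_numpy()) == 1.0

    def test_null_config_r2_matches_permutation_expectation(self):
        # with no signal, E[R^2] = (a-1)/(n-1) = 3/79 for 4 groups of 20
        r2s = []
        for rep in range(100):
            cfg = _null_config(seed=1000 + rep)
            ds, scheme, _, _ = generate_dataset(cfg)
            m = build_matrix(ds, list(cfg.traits))
            codes, _ = pd.factorize(scheme.assignment.loc[m.species])
            r2s.append(coordinate_r2(m.to_numpy(), codes))
        r2s = np.asarray(r2s)
        expected = 3 / 79
        se = r2s.std(ddof=1) / np.sqrt(len(r2s))
        assert abs(r2s.mean() - expected) < 3 * se

    def test_missingness_thins_complete_cases_binomially(self):
        cfg = SyntheticConfig(
            species_per_group=50,
            missing_fraction={"SLA": 0.5},
            records_per_species=(1, 1),
            n_sites=1,
            plots_per_site=1,
            seed=5,
        )
        ds, _, _, _ = generate_dataset(cfg)
        n_sla = ds.records[ds.records["trait_name"] == "SLA"]["species_name"].nunique()
        n, p = cfg.n_species, 0.5
        sd = np.sqrt(n * p * (1 - p))
        assert abs(n_sla - n * p) < 4 * sd

    def test_log_values_match_configured_moments(self):
        # one species, one trait, 10,000 records: sample moments of the
        # log10 values must match the configured normal
        cfg = SyntheticConfig(
            n_groups=1,
            species_per_group=1,
            traits=("SLA",),
            group_means={"g": [1.0]},
            trait_sd_between_species=0.0,
            within_species_sd=0.2,
            missing_fraction=0.0,
            records_per_species=(10_000, 10_000),
            n_sites=1,
            plots_per_site=1,
            seed=2,
        )
        ds, _, _, _ = generate_dataset(cfg)
        logs = np.log10(ds.records["value"].to_numpy())
        assert len(logs) == 10_000
        assert logs.mean() == pytest.approx(1.0, abs=0.01)
        assert logs.std(ddof=1) == pytest.approx(0.2, abs=0.01)
        from scipy.stats import skew

        assert abs(skew(logs)) < 0.1

    def test_cover_is_skewed_for_small_concentration(self):
        cfg = SyntheticConfig(
            species_per_group=25, abundance_shape=0.1, n_sites=2, plots_per_site=2, seed=3
        )
        _, _, cover, _ = generate_dataset(cfg)
        # even abundances would put every species at 1%; with a small
        # Dirichlet concentration the top species holds an order of
        # magnitude more cover in virtually every plot
        shares = cover.rows.groupby(["site", "plot", "year"])["cover"].max()
        assert (shares > 10).mean() > 0.8

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            SyntheticConfig(missing_fraction=1.0)
        with pytest.raises(ValidationError):
            SyntheticConfig(trait_sd_between_species=-0.1)
        with pytest.raises(ValidationError):
            SyntheticConfig(group_means={"a": [1.0]})


class TestExpectedSeparationR2:
    def test_null_config_is_zero(self):
        assert expected_separation_r2(_null_config()) == pytest.approx(0.0)

    def test_equal_between_and_within_variance_gives_half(self):
        # single trait, two groups at log-means 0 and 1: between-group
        # variance 0.25; between-species SD 0.5 contributes 0.25
        cfg = SyntheticConfig(
            n_groups=2,
            species_per_group=10,
            traits=("SLA",),
            group_means={"a": [0.0], "b": [1.0]},
            trait_sd_between_species=0.5,
            within_species_sd=0.0,
            missing_fraction=0.0,
            records_per_species=(1, 1),
            seed=0,
        )
        assert expected_separation_r2(cfg) == pytest.approx(0.5)

    def test_within_species_noise_attenuated_by_record_count(self):
        base = dict(
            n_groups=2,
            species_per_group=10,
            traits=("SLA",),
            group_means={"a": [0.0], "b": [1.0]},
            trait_sd_between_species=0.0,
            missing_fraction=0.0,
            seed=0,
        )
        one = SyntheticConfig(within_species_sd=0.5, records_per_species=(1, 1), **base)
        many = SyntheticConfig(within_species_sd=0.5, records_per_species=(25, 25), **base)
        assert expected_separation_r2(many) > expected_separation_r2(one)


def test_clustering_recovery_monotone_in_separation():
    """ARI of k-means vs the planted partition rises with group separation."""
    base_means = np.array(
        [
            [1.0, 0.0, 2.0, 0.6, -0.8, 0.9],
            [1.2, 0.1, 2.2, 0.9, -0.6, 1.1],
            [1.1, -0.2, 2.1, 1.2, -0.4, 1.3],
            [0.9, -0.4, 2.3, 1.5, -0.2, 1.5],
        ]
    )
    center = base_means.mean(axis=0)
    aris = []
    for scale in (0.2, 1.0, 3.0):
        means = center + scale * (base_means - center)
        vals = []
        for seed in range(5):
            cfg = SyntheticConfig(
                species_per_group=15,
                group_means={f"g{i}": list(means[i]) for i in range(4)},
                trait_sd_between_species=0.25,
                within_species_sd=0.05,
                missing_fraction=0.0,
                records_per_species=(2, 2),
                n_sites=1,
                plots_per_site=1,
                seed=100 + seed,
            )
            ds, scheme, _, _ = generate_dataset(cfg)
            m = build_matrix(ds, list(cfg.traits))
            codes, _ = pd.factorize(scheme.assignment.loc[m.species])
            km = kmeans_cluster(m, 4, n_init=10, seed=seed)
            vals.append(adjusted_rand_score(codes, km.partition.labels.to_numpy()))
        aris.append(np.mean(vals))
    assert aris[0] <= aris[1] + 0.05 and aris[1] <= aris[2] + 0.05
    assert aris[2] > aris[0]
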