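import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitclust import (
    Partition,
    ValidationError,
    coordinate_r2,
    euclidean_distances,
    pairwise_group_tests,
    pca,
    permanova,
)
from traitclust.stats import DistanceMatrix, exact_ranksum_p

from conftest import matrix_from_array


def _partition(labels, species=None):
    species = species or [f"sp{i}" for i in range(len(labels))]
    return Partition(labels=pd.Series(labels, index=species))


def _anova_oracle(x, codes):
    """Classical one-way ANOVA sums of squares on 1-D data."""
    x = np.asarray(x, dtype=float)
    sst = ((x - x.mean()) ** 2).sum()
    ssw = sum(((x[codes == g] - x[codes == g].mean()) ** 2).sum() for g in np.unique(codes))
    a, n = len(np.unique(codes)), len(x)
    ssb = sst - ssw
    f = (ssb / (a - 1)) / (ssw / (n - a))
    return ssb / sst, f


class TestEuclideanDistances:
    def test_three_four_five(self):
        m = matrix_from_array([[0, 0], [3, 4]])
        assert euclidean_distances(m).values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        m = matrix_from_array([[1, 2], [1, 2]])
        assert euclidean_distances(m).values[0, 1] == 0.0

    def test_one_dimensional_distances(self):
        m = matrix_from_array([0.0, 1.0, 3.0])
        d = euclidean_distances(m).values
        assert d[0, 1] == 1.0 and d[0, 2] == 3.0 and d[1, 2] == 2.0


class TestPermanova:
    def test_zero_within_group_distance(self):
        m = matrix_from_array([[0, 0], [0, 0], [1, 1], [1, 1]])
        res = permanova(euclidean_distances(m), _partition([0, 0, 1, 1]), 0)
        assert res.ss_within == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)
        assert np.isinf(res.pseudo_f)

    def test_one_dimensional_worked_example(self):
        # classical ANOVA: MS_between = 121.5/1, MS_within = 4/4 -> F = 121.5
        m = matrix_from_array([0.0, 1.0, 2.0, 9.0, 10.0, 11.0])
        res = permanova(euclidean_distances(m), _partition([0, 0, 0, 1, 1, 1]), 0)
        assert res.ss_total == pytest.approx(125.5)
        assert res.ss_within == pytest.approx(4.0)
        assert res.r_squared == pytest.approx(121.5 / 125.5)
        assert res.pseudo_f == pytest.approx(121.5)

    def test_all_points_identical_is_degenerate(self):
        m = matrix_from_array([[1, 1]] * 4)
        res = permanova(euclidean_distances(m), _partition([0, 0, 1, 1]), 99, seed=0)
        assert res.degenerate
        assert res.r_squared == 0.0

    def test_single_group_rejected(self):
        m = matrix_from_array([0.0, 1.0, 2.0])
        with pytest.raises(ValidationError):
            permanova(euclidean_distances(m), _partition([0, 0, 0]), 0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_classical_anova_on_one_trait(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        a = int(rng.integers(2, 5))
        codes = np.concatenate([np.arange(a), rng.integers(0, a, n - a)])
        x = rng.normal(size=n)
        res = permanova(euclidean_distances(matrix_from_array(x)), _partition(codes), 0)
        r2, f = _anova_oracle(x, codes)
        assert res.r_squared == pytest.approx(r2, abs=1e-9)
        assert res.pseudo_f == pytest.approx(f, abs=1e-9)

    def test_r_squared_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(15, 3))
        codes = rng.integers(0, 3, 15)
        theta = 0.7
        rot = np.eye(3)
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        moved = x @ rot.T + np.array([5.0, -2.0, 1.0])
        r1 = permanova(euclidean_distances(matrix_from_array(x)), _partition(codes), 0)
        r2 = permanova(euclidean_distances(matrix_from_array(moved)), _partition(codes), 0)
        assert r1.r_squared == pytest.approx(r2.r_squared, abs=1e-10)

    def test_full_enumeration_mean_r2_identity(self):
        # over all distinct label arrangements, mean R^2 = (a-1)/(n-1)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(6, 2))
        res = permanova(
            euclidean_distances(matrix_from_array(x)),
            _partition([0, 0, 1, 1, 2, 2]),
            999,
            return_permuted=True,
        )
        assert res.method == "enumerated"
        assert res.permuted_r2.mean() == pytest.approx(2 / 5, abs=1e-12)

    def test_sampled_p_reproducible_from_seed(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(24, 2))
        codes = np.repeat(np.arange(4), 6)
        dm = euclidean_distances(matrix_from_array(x))
        p1 = permanova(dm, _partition(codes), 199, seed=11, enumerate_threshold=0)
        p2 = permanova(dm, _partition(codes), 199, seed=11, enumerate_threshold=0)
        assert p1.p_value == p2.p_value
        assert p1.method == "sampled"

    def test_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(21)
        x = rng.normal(size=(20, 3))
        codes = np.repeat(np.arange(4), 5)
        m = matrix_from_array(x)
        dm = euclidean_distances(m)
        ours = permanova(dm, _partition(codes), 0)
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dm.values, ids=dm.labels),
            grouping=[str(c) for c in codes],
            permutations=0,
        )
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"], abs=1e-9)

    def test_coordinate_r2_equals_distance_route(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(18, 4))
        codes = rng.integers(0, 3, 18)
        codes[:3] = [0, 1, 2]
        res = permanova(euclidean_distances(matrix_from_array(x)), _partition(codes), 0)
        assert coordinate_r2(x, codes) == pytest.approx(res.r_squared, abs=1e-10)


class TestPCA:
    def test_perfectly_correlated_traits_load_on_pc1(self):
        x = np.array([[0, 0], [1, 2], [2, 4], [3, 6]], dtype=float)
        res = pca(matrix_from_array(x))
        assert res.variance_fraction[0] == pytest.approx(1.0)

    def test_matches_direct_eigendecomposition(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(10, 4))
        res = pca(matrix_from_array(x))
        cov = np.cov(x, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.variance_fraction, evals / evals.sum(), atol=1e-8
        )
        for j in range(4):  # loadings match up to sign
            dot = abs(res.loadings.to_numpy()[:, j] @ evecs[:, j])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_reconstruction_from_all_components(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(12, 3))
        res = pca(matrix_from_array(x))
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, x - x.mean(axis=0), atol=1e-8)

    def test_variance_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(20, 5)) * np.array([3, 2, 1.5, 1, 0.5])
        res = pca(matrix_from_array(x))
        assert res.variance_fraction.sum() == pytest.approx(1.0)
        assert np.all(np.diff(res.variance_fraction) <= 1e-12)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=(9, 3))
        res = pca(matrix_from_array(x))
        loadings = res.loadings.to_numpy()
        for j in range(loadings.shape[1]):
            assert loadings[np.argmax(np.abs(loadings[:, j])), j] > 0


class TestRankSumTests:
    def test_identical_multisets_give_p_one(self):
        assert exact_ranksum_p(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == 1.0

    def test_separated_groups_exact_p(self):
        # all 20 assignments of ranks; both one-sided extremes -> p = 2/20
        assert exact_ranksum_p(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == pytest.approx(0.1)

    def test_duplication_keeps_direction(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.5, 4, 5])
        p1 = exact_ranksum_p(x, y)
        p2 = exact_ranksum_p(np.repeat(x, 2), np.repeat(y, 2))
        assert p1 < 0.5 and p2 < 0.5

    def test_pairwise_table_covers_all_pairs_with_holm(self):
        rng = np.random.default_rng(12)
        values = pd.Series(rng.normal(size=12), index=[f"sp{i}" for i in range(12)])
        part = _partition([0] * 4 + [1] * 4 + [2] * 4, species=list(values.index))
        res = pairwise_group_tests(values, part, adjust="holm")
        assert len(res.table) == 3
        assert (res.table["adjusted_p"] >= res.table["p_value"] - 1e-12).all()
        assert ((res.table["p_value"] > 0) & (res.table["p_value"] <= 1)).all()

    def test_small_group_skipped(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        part = _partition([0, 0, 0, 1], species=list("abcd"))
        res = pairwise_group_tests(values, part)
        assert len(res.table) == 0

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=15)
        y = rng.normal(loc=2.0, size=15)
        values = pd.Series(np.concatenate([x, y]), index=[f"s{i}" for i in range(30)])
        part = _partition([0] * 15 + [1] * 15, species=list(values.index))
        res = pairwise_group_tests(values, part)
        assert res.table["p_value"].iloc[0] < 0.01
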