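import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from giniclust.clustering import (
    SINGLETON,
    correlation_distance,
    dbscan,
    jaccard_distance,
)


class TestJaccardDistance:
    def test_forced_examples(self):
        # profiles over 3 genes: (1,1,0) vs (1,0,1) share 1 of 3 -> 2/3
        vals = np.array([[1, 1], [1, 0], [0, 1]], dtype=float)
        d = jaccard_distance(vals)
        assert d[0, 1] == pytest.approx(2 / 3)

    def test_identical_and_disjoint_profiles(self):
        vals = np.array([[2, 2, 0], [1, 1, 0], [0, 0, 3]], dtype=float)
        d = jaccard_distance(vals)
        assert d[0, 1] == 0.0
        assert d[0, 2] == 1.0

    def test_empty_cells_warn_and_sit_at_zero_distance(self):
        vals = np.array([[1, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.warns(UserWarning, match="detect none"):
            d = jaccard_distance(vals)
        assert d[1, 2] == 0.0
        assert d[0, 1] == 1.0

    @given(
        st.lists(
            st.lists(st.booleans(), min_size=4, max_size=4),
            min_size=3,
            max_size=8,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_metric_axioms_and_triangle_inequality(self, profiles):
        vals = np.array(profiles, dtype=float).T  # genes x cells
        d = jaccard_distance(vals)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


class TestCorrelationDistance:
    def test_perfectly_correlated_cells(self):
        vals = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        d = correlation_distance(vals)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_cells_reach_one_after_rescale(self):
        vals = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
        d = correlation_distance(vals)
        assert d[0, 1] == pytest.approx(1.0)
        assert correlation_distance(vals, rescale=False)[0, 1] == pytest.approx(2.0)

    def test_orthogonal_profiles_at_half(self):
        a = np.array([1.0, -1.0, 1.0, -1.0])
        b = np.array([1.0, 1.0, -1.0, -1.0])
        assert float(np.corrcoef(a, b)[0, 1]) == pytest.approx(0.0)
        d = correlation_distance(np.column_stack([a, b]) + 2.0)
        assert d[0, 1] == pytest.approx(0.5)

    def test_zero_variance_cell_is_an_error(self):
        vals = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        with pytest.raises(ValueError, match="zero variance"):
            correlation_distance(vals)


def block_distance(sizes, within=0.1, between=0.9):
    n = sum(sizes)
    d = np.full((n, n), between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestDbscan:
    def test_two_separable_groups(self):
        d = block_distance([10, 10])
        a = dbscan(d, eps=0.5, min_pts=3)
        assert a.n_clusters == 2
        assert a.n_singletons == 0
        assert sorted(a.sizes.values()) == [10, 10]

    def test_isolated_point_is_singleton(self):
        d = block_distance([10])
        d = np.pad(d, ((0, 1), (0, 1)), constant_values=0.95)
        d[-1, -1] = 0.0
        a = dbscan(d, eps=0.5, min_pts=3)
        assert a.n_clusters == 1
        assert a.labels[-1] == SINGLETON

    def test_cluster_ids_ordered_by_size_and_rare_flag(self):
        # sizes 50 and 4 out of 54 cells: cluster 2 is rare (< 5%... 4/54 = 7.4%)
        d = block_distance([4, 50, 3])
        names = [f"x{i}" for i in range(57)]
        a = dbscan(d, eps=0.5, min_pts=3, cell_names=names)
        assert a.sizes[1] == 50
        assert set(a.sizes.values()) == {50, 4, 3}
        cutoff = 0.05 * 57
        for cid, size in a.sizes.items():
            assert (cid in a.rare_ids) == (size < cutoff)

    def test_every_cluster_has_at_least_min_pts_members(self):
        rng = np.random.default_rng(0)
        pts = rng.random((60, 2))
        d = squareform(pdist(pts))
        d = d / d.max()
        for eps in (0.05, 0.1, 0.2):
            a = dbscan(d, eps=eps, min_pts=4)
            assert all(s >= 4 for s in a.sizes.values())

    def test_label_invariance_under_cell_permutation(self):
        rng = np.random.default_rng(1)
        d = block_distance([12, 5, 7], within=0.2, between=0.8)
        n = d.shape[0]
        noise = rng.uniform(0, 0.05, size=(n, n))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = d + noise
        names = [f"cell{i}" for i in range(n)]
        a = dbscan(d, eps=0.5, min_pts=3, cell_names=names)
        perm = rng.permutation(n)
        ap = dbscan(
            d[np.ix_(perm, perm)], eps=0.5, min_pts=3,
            cell_names=[names[i] for i in perm],
        )
        ref = dict(zip(a.cell_names, a.labels))
        got = dict(zip(ap.cell_names, ap.labels))
        assert ref == got

    def test_singletons_decrease_as_eps_grows(self, small_nb):
        """Raising eps can only connect more cells, never fewer."""
        from giniclust import RunConfig, run_pipeline

        m, _ = small_nb
        res = run_pipeline(m, RunConfig(min_genes=0, de=False))
        from giniclust.clustering import jaccard_distance as jd
        import warnings

        sub = res.matrix.subset_genes(
            res.gini_table["selected"].to_numpy()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = jd(sub.values)
        counts = [
            dbscan(d, eps=e, min_pts=3).n_singletons
            for e in (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_agrees_with_reference_dbscan_on_core_points(self):
        """Core-point clustering matches scikit-learn's DBSCAN; only the
        (deliberately deterministic) border assignment may differ."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(2)
        pts = np.vstack(
            [rng.normal(0, 0.08, (25, 2)), rng.normal(1, 0.08, (30, 2)),
             rng.uniform(-1, 2, (10, 2))]
        )
        d = squareform(pdist(pts))
        eps, min_pts = 0.15, 4
        ours = dbscan(d, eps=eps, min_pts=min_pts)
        sk = SkDBSCAN(eps=eps, min_samples=min_pts, metric="precomputed").fit(d)
        core = np.zeros(len(pts), dtype=bool)
        core[sk.core_sample_indices_] = True
        # same core sets
        within = d <= eps
        np.fill_diagonal(within, True)
        assert np.array_equal(within.sum(1) >= min_pts, core)
        # same partition of core points
        for i in np.flatnonzero(core):
            for j in np.flatnonzero(core):
                assert (ours.labels[i] == ours.labels[j]) == (
                    sk.labels_[i] == sk.labels_[j]
                )
        # same noise set
        np.testing.assert_array_equal(
            ours.labels == SINGLETON, sk.labels_ == -1
        )

    def test_parameter_validation(self):
        d = block_distance([5])
        with pytest.raises(ValueError, match="eps"):
            dbscan(d, eps=0, min_pts=3)
        with pytest.raises(ValueError, match="min_pts"):
            dbscan(d, eps=0.5, min_pts=0)
        with pytest.raises(ValueError, match="symmetric"):
            dbscan(np.array([[0, 1.0], [0.5, 0]]), eps=0.5, min_pts=2)
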