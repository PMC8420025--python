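import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from tpakit.structure import cut_tree, hierarchical_cluster, pca, to_newick

from conftest import make_log_matrix


def lance_williams_average_oracle(X):
    """Average-linkage merge heights by direct recomputation of the recurrence."""
    n = X.shape[0]
    d = {
        (i, j): float(np.linalg.norm(X[i] - X[j]))
        for i in range(n)
        for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        # average linkage: d(k, ij) = (ni*d(k,i) + nj*d(k,j)) / (ni+nj)
        for k in active - {i, j}:
            dki = d[tuple(sorted((k, i)))]
            dkj = d[tuple(sorted((k, j)))]
            d[tuple(sorted((k, next_id)))] = (
                sizes[i] * dki + sizes[j] * dkj
            ) / (sizes[i] + sizes[j])
        for k in list(d):
            if i in k or j in k:
                del d[k]
        sizes[next_id] = sizes[i] + sizes[j]
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return heights


class TestPca:
    def test_rank_one_data_explained_by_first_component(self):
        pattern = np.array([1.0, 3.0, -2.0, 0.5, 4.0])
        X = np.outer(pattern, [1.0, 2.0, 3.0])  # proteins x runs, rank 1
        X += np.array([5.0, 1.0, 0.0, 2.0, 3.0])[:, None]  # per-protein offset
        res = pca(make_log_matrix(X), n_components=2)
        assert res.explained_variance_fraction[0] > 1 - 1e-10

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(0)
        res = pca(make_log_matrix(rng.normal(0, 1, (30, 8))), n_components=4)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(4), atol=1e-8)

    def test_explained_fractions_non_increasing_and_bounded(self):
        rng = np.random.default_rng(1)
        res = pca(make_log_matrix(rng.normal(0, 1, (40, 10))), n_components=6)
        ev = res.explained_variance_fraction
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1 + 1e-12

    def test_explained_fractions_match_covariance_eigenvalues(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (15, 6))  # proteins x runs
        res = pca(make_log_matrix(X), n_components=5)
        centered = (X - X.mean(axis=1, keepdims=True)).T  # runs x proteins
        cov = centered.T @ centered / (centered.shape[0] - 1)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            res.explained_variance_fraction, (eig / eig.sum())[:5], atol=1e-10
        )

    def test_reconstruction_with_all_components(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (20, 6))
        res = pca(make_log_matrix(X), n_components=6)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        centered = (X - X.mean(axis=1, keepdims=True)).T
        assert np.linalg.norm(recon - centered) < 1e-8

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (25, 7))
        r1 = pca(make_log_matrix(X), n_components=3)
        r2 = pca(make_log_matrix(X), n_components=3)
        pd.testing.assert_frame_equal(r1.scores, r2.scores)
        for j in range(3):
            col = r1.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_group_separation_on_pc1(self):
        rng = np.random.default_rng(5)
        X = rng.normal(20, 0.2, (50, 6))
        X[:25, :3] += 3.0  # two well-separated run groups
        res = pca(make_log_matrix(X), n_components=2)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = pc1[:3], pc1[3:]
        gap = abs(a.mean() - b.mean())
        assert gap > a.std() + b.std()  # silhouette-like separation

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="n_components"):
            pca(make_log_matrix(rng.normal(0, 1, (10, 4))), n_components=5)


class TestHierarchicalCluster:
    def test_nearest_pair_merges_first(self):
        X = np.array([[0.0], [1.0], [10.0]])
        tree = hierarchical_cluster(
            make_log_matrix(X.T, run_ids=["a", "b", "c"]), axis="runs"
        )
        first = tree.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_duplicates_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]])
        tree = hierarchical_cluster(
            make_log_matrix(X.T, run_ids=list("abc")), axis="runs"
        )
        assert tree.linkage[0, 2] == 0.0

    def test_average_linkage_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (20, 5))  # 20 items in 5 dims
        tree = hierarchical_cluster(
            make_log_matrix(X.T, run_ids=[f"r{i}" for i in range(20)]), axis="runs"
        )
        expected = lance_williams_average_oracle(X)
        np.testing.assert_allclose(tree.merge_heights, expected, rtol=1e-10)

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        for linkage in ("average", "complete", "single", "ward"):
            tree = hierarchical_cluster(
                make_log_matrix(rng.normal(0, 1, (12, 6))), axis="proteins",
                linkage=linkage,
            )
            assert (np.diff(tree.merge_heights) >= -1e-12).all()

    def test_permutation_invariant_heights(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (15, 4))
        perm = rng.permutation(15)
        t1 = hierarchical_cluster(make_log_matrix(X), axis="proteins")
        t2 = hierarchical_cluster(make_log_matrix(X[perm]), axis="proteins")
        np.testing.assert_allclose(
            np.sort(t1.merge_heights), np.sort(t2.merge_heights), rtol=1e-10
        )

    def test_single_item_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(make_log_matrix([[1.0], [2.0]]), axis="runs")


class TestCutTree:
    def _tree(self, n=6):
        rng = np.random.default_rng(10)
        return hierarchical_cluster(
            make_log_matrix(rng.normal(0, 1, (8, n))), axis="runs"
        )

    def test_k_equals_n_gives_singletons(self):
        t = self._tree()
        labels = cut_tree(t, 6)
        assert labels.nunique() == 6

    def test_k_one_gives_single_group(self):
        assert cut_tree(self._tree(), 1).nunique() == 1

    def test_two_blob_split(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 0.1, (10, 8))
        X[:, 4:] += 5.0
        t = hierarchical_cluster(
            make_log_matrix(X, run_ids=[f"r{i}" for i in range(8)]), axis="runs"
        )
        labels = cut_tree(t, 2)
        assert labels.iloc[:4].nunique() == 1
        assert labels.iloc[4:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[4]


class TestNewick:
    def test_round_trip_through_scikit_bio(self):
        import io

        import skbio

        rng = np.random.default_rng(12)
        tree = hierarchical_cluster(
            make_log_matrix(rng.normal(0, 1, (10, 5)), run_ids=list("abcde")),
            axis="runs",
        )
        text = to_newick(tree)
        parsed = skbio.TreeNode.read(io.StringIO(text))
        assert sorted(t.name for t in parsed.tips()) == list("abcde")
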