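"""UPGMA, Newick serialization, PCoA, and trait standardization/PCA."""

import numpy as np
import pandas as pd
import pytest

from melodiv.clustering import cut_tree, pca, pcoa, standardize, to_newick, upgma
from melodiv.data_model import DataError, DistanceMatrix


def naive_upgma_heights(labels, values):
    """Brute-force oracle: recompute every cluster pair distance from the
    original matrix by averaging over all cross-cluster leaf pairs (no
    Lance-Williams update), with the same lexicographic tie-break.

    Returns {frozenset(leaves): height} for every internal node.
    """
    d0 = {(a, b): values[i, j] for i, a in enumerate(labels) for j, b in enumerate(labels)}
    clusters = {lab: frozenset([lab]) for lab in labels}
    heights = {}
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x_i, x in enumerate(keys):
            for y in keys[x_i + 1:]:
                cx, cy = clusters[x], clusters[y]
                dist = np.mean([d0[(a, b)] for a in cx for b in cy])
                cand = (dist, x, y)
                if best is None or cand < best:
                    best = cand
        dist, x, y = best
        merged = clusters[x] | clusters[y]
        heights[merged] = dist / 2.0
        del clusters[x], clusters[y]
        clusters[min(x, y)] = merged
    return heights


def tree_heights(tree):
    out = {}

    def walk(node):
        if node.is_leaf:
            return frozenset([node.label])
        members = frozenset()
        for c in node.children:
            members |= walk(c)
        out[members] = node.height
        return members

    walk(tree.root)
    return out


class TestUpgma:
    def test_two_leaves(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        t = upgma(d)
        assert t.root.height == pytest.approx(0.2)
        assert sorted(t.leaves()) == ["A", "B"]

    def test_three_leaf_hand_example(self):
        vals = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        t = upgma(DistanceMatrix(["A", "B", "C"], vals))
        h = tree_heights(t)
        assert h[frozenset("AB")] == pytest.approx(0.1)
        assert h[frozenset("ABC")] == pytest.approx(0.3)

    def test_matches_naive_rescan_oracle(self):
        rng = np.random.default_rng(3)
        labels = [f"T{i}" for i in range(6)]
        for _ in range(20):
            x = rng.random((6, 3))
            vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            d = DistanceMatrix(labels, vals)
            assert tree_heights(upgma(d)) == pytest.approx(
                naive_upgma_heights(labels, vals)
            )

    def test_ultrametric_matrix_recovered_exactly(self):
        # tree ((A,B):0.3,(C,D):0.2):..., cophenetic distances are ultrametric
        vals = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.4],
                [0.8, 0.8, 0.4, 0.0],
            ]
        )
        t = upgma(DistanceMatrix(list("ABCD"), vals))
        h = tree_heights(t)
        assert h[frozenset("AB")] == pytest.approx(0.1)
        assert h[frozenset("CD")] == pytest.approx(0.2)
        assert h[frozenset("ABCD")] == pytest.approx(0.4)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.random((5, 2))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(5)]
        t1 = tree_heights(upgma(DistanceMatrix(labels, vals)))
        perm = rng.permutation(5)
        t2 = tree_heights(
            upgma(DistanceMatrix([labels[i] for i in perm], vals[np.ix_(perm, perm)]))
        )
        assert t1 == pytest.approx(t2)

    def test_nan_rejected(self):
        vals = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(DataError, match="NaN"):
            upgma(DistanceMatrix(["A", "B"], vals))


class TestNewick:
    def test_two_leaf_string(self):
        d = DistanceMatrix(["A", "B"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert to_newick(upgma(d)) == "(A:0.2,B:0.2);"

    def test_single_leaf(self):
        t = upgma(DistanceMatrix(["A"], np.zeros((1, 1))))
        assert to_newick(t) == "A;"

    def test_roundtrip_through_dendropy(self):
        import dendropy

        rng = np.random.default_rng(4)
        x = rng.random((6, 2))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"T{i}" for i in range(6)]
        t = upgma(DistanceMatrix(labels, vals))
        nw = to_newick(t, precision=12)
        parsed = dendropy.Tree.get(data=nw, schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        heights = tree_heights(t)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                # cophenetic distance = 2 x merge height
                merged = min(
                    (m for m in heights if a in m and b in m), key=len
                )
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                    2 * heights[merged], abs=1e-9
                )


class TestCutTree:
    def test_singletons_and_one_cluster(self):
        rng = np.random.default_rng(0)
        x = rng.random((4, 2))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        t = upgma(DistanceMatrix(list("ABCD"), vals))
        assert set(cut_tree(t, 4).values()) == {0, 1, 2, 3}
        assert set(cut_tree(t, 1).values()) == {0}

    def test_two_blob_cut(self):
        vals = np.array(
            [
                [0.0, 0.1, 1.0, 1.1],
                [0.1, 0.0, 1.2, 1.0],
                [1.0, 1.2, 0.0, 0.1],
                [1.1, 1.0, 0.1, 0.0],
            ]
        )
        labels = cut_tree(upgma(DistanceMatrix(list("ABCD"), vals)), 2)
        assert labels["A"] == labels["B"]
        assert labels["C"] == labels["D"]
        assert labels["A"] != labels["C"]


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([0.0, 3.0, 5.0])
        vals = np.abs(pts[:, None] - pts[None])
        res = pcoa(DistanceMatrix(["a", "b", "c"], vals), n_axes=1)
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        coords = res.coordinates.to_numpy()
        rec = np.abs(coords[:, 0][:, None] - coords[:, 0][None])
        np.testing.assert_allclose(rec, vals, atol=1e-9)

    def test_euclidean_distances_recovered(self):
        rng = np.random.default_rng(7)
        x = rng.random((8, 4))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(8)], vals), n_axes=4)
        coords = res.coordinates.to_numpy()
        rec = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        np.testing.assert_allclose(rec, vals, atol=1e-8)

    def test_zero_distances_zero_eigenvalues(self):
        with pytest.warns(UserWarning, match="positive eigenvalues"):
            res = pcoa(DistanceMatrix(list("abc"), np.zeros((3, 3))), n_axes=2)
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)
        assert res.coordinates.shape[1] == 0

    def test_eigenvalues_descending(self):
        rng = np.random.default_rng(8)
        x = rng.random((6, 3))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"s{i}" for i in range(6)], vals))
        assert np.all(np.diff(res.eigenvalues) <= 1e-12)

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(21)
        x = rng.random((7, 3))
        vals = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"s{i}" for i in range(7)]
        mine = pcoa(DistanceMatrix(labels, vals), n_axes=3)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(vals, ids=labels))
        np.testing.assert_allclose(
            np.sort(mine.eigenvalues[mine.eigenvalues > 1e-9])[::-1],
            np.sort(ref.eigvals.to_numpy()[ref.eigvals.to_numpy() > 1e-9])[::-1],
            atol=1e-8,
        )
        for k in range(3):
            a = mine.coordinates.to_numpy()[:, k]
            b = ref.samples.to_numpy()[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8


class TestStandardize:
    def test_columns_centered_scaled(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 8.0], "y": [0.0, 5.0, 5.0, 2.0]})
        z = standardize(df)
        np.testing.assert_allclose(z.mean(), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=1), 1.0, atol=1e-12)

    def test_two_point_column(self):
        z = standardize(pd.DataFrame({"x": [0.0, 2.0], "y": [1.0, 3.0]}))
        np.testing.assert_allclose(z["x"], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DataError, match="flat"):
            standardize(df)


class TestPca:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(20, 5)))
        res = pca(standardize(df), n_axes=5)
        assert res.variance_explained.sum() == pytest.approx(1.0)

    def test_perfectly_correlated_single_component(self):
        x = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        res = pca(standardize(df), n_axes=2)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_pca_scores_match_pcoa_of_euclidean_distances(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(12, 4)))
        z = standardize(df)
        res_pca = pca(z, n_axes=4)
        vals = np.sqrt(((z.to_numpy()[:, None] - z.to_numpy()[None]) ** 2).sum(-1))
        res_pcoa = pcoa(DistanceMatrix([str(i) for i in z.index], vals), n_axes=4)
        a = res_pca.coordinates.to_numpy()
        b = res_pcoa.coordinates.to_numpy()
        da = np.sqrt(((a[:, None] - a[None]) ** 2).sum(-1))
        db = np.sqrt(((b[:, None] - b[None]) ** 2).sum(-1))
        np.testing.assert_allclose(da, db, atol=1e-8)

    def test_single_sample_rejected(self):
        with pytest.raises(DataError):
            pca(pd.DataFrame({"a": [1.0]}), n_axes=1)
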