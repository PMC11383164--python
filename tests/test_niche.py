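"""Transcriptomics filtering, normalisation, cell typing, and niches."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from gbmspatial.niche import (
    cluster_cell_types,
    filter_cells,
    kmeans_niches,
    neighborhood_composition,
    niche_type_outliers,
    normalize_expression,
)


def _counts(mat, genes=None):
    mat = np.asarray(mat)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    return pd.DataFrame(mat, index=genes, columns=[f"c{i}" for i in range(mat.shape[1])])


class TestFilterCells:
    def test_feature_threshold_inclusive(self):
        mat = np.zeros((6, 2), dtype=int)
        mat[:4, 0] = 3  # 4 detected genes -> removed
        mat[:5, 1] = 1  # 5 genes at count 1 -> kept
        out = filter_cells(_counts(mat))
        assert list(out.columns) == ["c1"]

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            filter_cells(_counts(np.zeros((5, 3), dtype=int)))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.poisson(0.8, (30, 50)))
        once = filter_cells(counts)
        pd.testing.assert_frame_equal(filter_cells(once), once)


class TestNormalize:
    def test_proportional_cells_identical(self):
        counts = _counts(np.array([[2, 4], [6, 12], [0, 0]]))
        norm = normalize_expression(counts)
        assert np.allclose(norm["c0"], norm["c1"])

    def test_explicit_target_halves_larger_library(self):
        counts = _counts(np.array([[100], [0]])).join(
            _counts(np.array([[200], [0]])).rename(columns={"c0": "c1"})
        )
        norm = normalize_expression(counts, target_sum=100)
        assert norm.loc["g0", "c0"] == pytest.approx(np.log1p(100))
        assert norm.loc["g0", "c1"] == pytest.approx(np.log1p(100))

    def test_zeros_stay_zero_and_order_kept(self):
        rng = np.random.default_rng(1)
        counts = _counts(rng.poisson(2.0, (20, 15)) * rng.integers(0, 2, (20, 15)))
        counts = filter_cells(counts)
        norm = normalize_expression(counts)
        assert ((counts.to_numpy() == 0) == (norm.to_numpy() == 0)).all()
        assert list(norm.columns) == list(counts.columns)

    def test_zscore_constant_gene_zero(self):
        # equal libraries keep the constant gene constant after scaling
        counts = _counts(np.array([[5, 5, 5], [3, 3, 3]]))
        z = normalize_expression(counts, mode="zscore")
        assert np.allclose(z.loc["g0"], 0.0)


class TestCellTyping:
    def test_disjoint_signatures_recovered(self):
        rng = np.random.default_rng(0)
        n = 150
        a = np.vstack([rng.poisson(8.0, (5, n)), rng.poisson(0.1, (5, n))])
        b = np.vstack([rng.poisson(0.1, (5, n)), rng.poisson(8.0, (5, n))])
        counts = _counts(np.hstack([a, b]))
        counts.columns = [f"c{i}" for i in range(2 * n)]
        norm = normalize_expression(filter_cells(counts))
        labels, markers = cluster_cell_types(norm, resolution=0.1, seed=0)
        truth = [0] * n + [1] * n
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels) == 1.0
        # the private marker block tops its cluster's marker list
        top = markers[markers.cluster == labels.iloc[0]].iloc[0]["names"]
        assert int(top[1:]) < 5

    def test_planted_tissue_recovery(self, niche_tissue):
        cells, counts = niche_tissue["cells"], niche_tissue["counts"]
        sub = np.random.default_rng(0).choice(len(cells), 1500, replace=False)
        counts_s = counts.iloc[:, sub]
        norm = normalize_expression(filter_cells(counts_s))
        labels, _ = cluster_cell_types(norm, seed=0)
        truth = cells.set_index("cell_id").loc[norm.columns, "true_type"]
        assert adjusted_rand_score(truth, labels) >= 0.8

    def test_constant_matrix_raises(self):
        with pytest.raises(ValueError):
            cluster_cell_types(_counts(np.ones((10, 20))))


class TestComposition:
    def test_homogeneous_tissue(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (50, 2))
        comp = neighborhood_composition(pts, ["T"] * 50, k=10)
        assert (comp["T"] == 10).all()

    def test_rows_sum_to_k(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (100, 2))
        labels = rng.choice(["A", "B", "C"], 100)
        comp = neighborhood_composition(pts, labels, k=15)
        assert (comp.sum(axis=1) == 15).all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        n, k = 300, 30
        pts = rng.uniform(0, 500, (n, 2))
        labels = rng.choice(["A", "B", "C", "D"], n)
        comp = neighborhood_composition(pts, labels, k=k)
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        types = sorted(set(labels))
        for i in rng.choice(n, 40, replace=False):
            order = np.lexsort((np.arange(n), np.round(dist[i], 9)))
            order = order[order != i][:k]
            expected = pd.Series(labels[order]).value_counts()
            for t in types:
                assert comp.loc[i, t] == expected.get(t, 0)

    def test_too_few_cells_raise(self):
        with pytest.raises(ValueError):
            neighborhood_composition(np.random.random((10, 2)), ["A"] * 10, k=30)


class TestNiches:
    def test_three_pure_blobs(self):
        rng = np.random.default_rng(0)
        blobs = [
            (rng.normal((0, 0), 5, (100, 2)), "A"),
            (rng.normal((500, 0), 5, (100, 2)), "B"),
            (rng.normal((0, 500), 5, (100, 2)), "C"),
        ]
        pts = np.vstack([b[0] for b in blobs])
        labels = sum([[b[1]] * 100 for b in blobs], [])
        comp = neighborhood_composition(pts, labels, k=30)
        niches, summary = kmeans_niches(comp, 3, seed=0)
        truth = np.repeat([0, 1, 2], 100)
        assert adjusted_rand_score(truth, niches) == 1.0
        assert summary.shape == (3, 3)

    def test_single_niche(self):
        comp = pd.DataFrame(np.random.default_rng(1).random((40, 3)))
        niches, _ = kmeans_niches(comp, 1)
        assert set(niches) == {1}

    def test_translation_rotation_stable(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 200, (200, 2))
        labels = rng.choice(["A", "B"], 200)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        c1 = neighborhood_composition(pts, labels, k=20)
        c2 = neighborhood_composition(pts @ R.T + 77.0, labels, k=20)
        assert np.array_equal(c1.to_numpy(), c2.to_numpy())

    def test_fewer_rows_than_niches(self):
        with pytest.raises(ValueError):
            kmeans_niches(pd.DataFrame(np.random.random((3, 2))), n_niches=7)


class TestOutliers:
    def test_concentrated_type_flagged(self):
        tab = pd.DataFrame(
            {"A": [500, 0, 0], "B": [160, 170, 170]}, index=[1, 2, 3]
        )
        res = niche_type_outliers(tab).set_index(["niche", "cell_type"])
        assert res.loc[(1, "A"), "flagged"]
        assert not res.loc[(2, "A"), "flagged"]
        assert not res.loc[(3, "A"), "flagged"]

    def test_uniform_type_not_flagged(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(3000, [0.25] * 4, size=3)
        tab = pd.DataFrame(counts, columns=list("ABCD"), index=[1, 2, 3])
        res = niche_type_outliers(tab, alpha=0.001)
        assert not res.flagged.any()
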