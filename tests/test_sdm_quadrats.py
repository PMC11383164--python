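"""Quadrat counting, scaling/splitting, and SMOTE balancing."""

import numpy as np
import pandas as pd
import pytest

from gbmspatial.sdm import QuadratGrid, quadrat_count, scale_and_split, smote_balance
from gbmspatial.sdm.quadrats import SDM_CATEGORIES, cell_sdm_category


def _classified(xy, categories, fov="fov_0"):
    """Minimal classified table whose SDM category is forced per cell."""
    n = len(xy)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "fov_id": fov,
            "x": [p[0] for p in xy],
            "y": [p[1] for p in xy],
            "excluded": False,
            "mutation_class": "WT",
        }
    )
    phen, geno = [], []
    for c in categories:
        if c in ("immune", "endothelial"):
            phen.append(c); geno.append("none")
        elif c == "EC-mimicry":
            phen.append("EC-mimicry tumor"); geno.append("EGFR-only")
        elif c == "TERTp-mutant":
            phen.append("tumor"); geno.append("none")
        elif c == "unclassified":
            phen.append("unclassified"); geno.append("none")
        else:
            phen.append("tumor"); geno.append(c)
    df["phenotype_class"] = phen
    df["genotype_class"] = geno
    df.loc[df["phenotype_class"].eq("tumor") & df["genotype_class"].eq("none"),
           "mutation_class"] = "MUT"
    return df


class TestQuadratCount:
    def _annotation(self, grid):
        rows = [
            {"qx": ix, "qy": iy, "texture": "mossy"}
            for iy in range(grid.ny)
            for ix in range(grid.nx)
        ]
        return pd.DataFrame(rows)

    def test_empty_quadrat_zero_vector(self):
        grid = QuadratGrid(398, 398, 199)
        cells = _classified([(10, 10)], ["immune"])
        out = quadrat_count(cells, grid, self._annotation(grid))
        empty = out[(out.qx == 1) & (out.qy == 1)]
        assert (empty[list(SDM_CATEGORIES)].to_numpy() == 0).all()

    def test_half_open_boundary_goes_right(self):
        grid = QuadratGrid(398, 398, 199)
        cells = _classified([(199.0, 10.0)], ["immune"])
        out = quadrat_count(cells, grid, self._annotation(grid))
        assert out.loc[(out.qx == 1) & (out.qy == 0), "immune"].iloc[0] == 1
        assert out.loc[(out.qx == 0) & (out.qy == 0), "immune"].iloc[0] == 0

    def test_count_conservation_oracle(self):
        rng = np.random.default_rng(0)
        n = 200
        xy = rng.uniform(0, 995, (n, 2)) * np.array([1.0, 597.0 / 995.0])
        cats = rng.choice([c for c in SDM_CATEGORIES if c != "all-tumor"], n)
        grid = QuadratGrid(995, 597, 199)
        cells = _classified(list(map(tuple, xy)), cats)
        out = quadrat_count(cells, grid, self._annotation(grid))
        qx, qy = grid.assign(cells["x"].to_numpy(), cells["y"].to_numpy())
        in_grid = qx >= 0
        for c in SDM_CATEGORIES[:-1]:
            assert out[c].sum() == ((cats == c) & in_grid).sum()
        tumor_cats = set(SDM_CATEGORIES[:8]) | {"EC-mimicry"}
        assert out["all-tumor"].sum() == (
            np.isin(cats, list(tumor_cats)) & in_grid
        ).sum()

    def test_unlabeled_quadrats_dropped_with_warning(self):
        grid = QuadratGrid(398, 199, 199)
        cells = _classified([(10, 10), (250, 10)], ["immune", "immune"])
        ann = pd.DataFrame([{"qx": 0, "qy": 0, "texture": "spotty"}])
        with pytest.warns(UserWarning):
            out = quadrat_count(cells, grid, ann)
        assert len(out) == 1

    def test_mask_mode_label_at_center(self):
        grid = QuadratGrid(398, 199, 199)
        mask = np.zeros((199, 398), dtype=int)
        mask[:, 199:] = 1
        cells = _classified([(10, 10)], ["immune"])
        out = quadrat_count(cells, grid, mask, texture_classes=("mossy", "spotty"))
        assert out.sort_values("qx")["texture"].tolist() == ["mossy", "spotty"]


def test_cell_category_mapping_matches_generator(sdm_cohort):
    """>=90% of cells map back to their generative type despite count noise."""
    cat = cell_sdm_category(sdm_cohort["classified"])
    truth = sdm_cohort["truth"].cell_types
    comparable = truth != "unclassified"
    agree = (cat[comparable.to_numpy()] == truth[comparable]).mean()
    assert agree > 0.9


class TestScaleAndSplit:
    def test_cohort_scale_split_arithmetic(self):
        X = np.random.default_rng(0).random((1270, 12))
        y = np.zeros(1270, dtype=int)
        s = scale_and_split(X, y, seed=0)
        assert len(s["train"]) == 1016
        assert len(s["val"]) == 127
        assert len(s["test"]) == 127

    def test_minimum_size_split(self):
        s = scale_and_split(np.random.random((10, 3)), np.zeros(10), seed=1)
        assert (len(s["train"]), len(s["val"]), len(s["test"])) == (8, 1, 1)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            scale_and_split(np.random.random((9, 3)), np.zeros(9))

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError):
            scale_and_split(np.random.random((20, 3)), np.zeros(20), (0.5, 0.2, 0.2))

    def test_scaling_bounds_and_disjoint_cover(self):
        X = np.random.default_rng(2).normal(10, 5, (100, 4))
        s = scale_and_split(X, np.zeros(100), seed=2)
        assert s["X"].min() >= 0 and s["X"].max() <= 1
        allidx = np.concatenate([s["train"], s["val"], s["test"]])
        assert len(allidx) == 100 and len(np.unique(allidx)) == 100

    def test_constant_feature_scaled_to_zero(self):
        X = np.random.default_rng(3).random((20, 3))
        X[:, 1] = 4.2
        with pytest.warns(UserWarning):
            s = scale_and_split(X, np.zeros(20), seed=0)
        assert (s["X"][:, 1] == 0).all()


class TestSmote:
    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = rng.random((60, 4))
        y = np.repeat([0, 1, 2], 20)
        Xa, ya, syn = smote_balance(X, y, seed=0)
        assert np.array_equal(Xa, X) and not syn.any()

    def test_balancing_contract(self):
        rng = np.random.default_rng(1)
        X = rng.random((200, 4))
        y = np.array([0] * 100 + [1] * 50 + [2] * 50)
        Xa, ya, syn = smote_balance(X, y, seed=1)
        assert np.bincount(ya).tolist() == [100, 100, 100]
        assert syn.sum() == 100
        assert not syn[: len(y)].any()

    def test_synthetic_points_on_segments(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.random((40, 3)), rng.random((10, 3)) + 5])
        y = np.array([0] * 40 + [1] * 10)
        Xa, ya, syn = smote_balance(X, y, seed=2)
        members = X[y == 1]
        for p in Xa[syn]:
            # distance from p to the nearest segment between two class members
            best = np.inf
            for i in range(len(members)):
                for j in range(len(members)):
                    if i == j:
                        continue
                    a, b = members[i], members[j]
                    t = np.clip(np.dot(p - a, b - a) / np.dot(b - a, b - a), 0, 1)
                    best = min(best, np.linalg.norm(p - (a + t * (b - a))))
            assert best < 1e-9

    def test_small_class_reduces_k_with_warning(self):
        X = np.random.default_rng(3).random((23, 2))
        y = np.array([0] * 20 + [1] * 3)
        with pytest.warns(UserWarning):
            Xa, ya, _ = smote_balance(X, y, k_neighbors=5, seed=3)
        assert np.bincount(ya).tolist() == [20, 20]


def test_batch_arithmetic_eleven_batches():
    """The balanced cohort training set splits into 11 equal mini-batches."""
    batches = np.array_split(np.arange(1793), 11)
    assert [len(b) for b in batches] == [163] * 11
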