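"""Spatial networks, proximity enrichment, and binarised coherence."""

import numpy as np
import pandas as pd
import pytest

from gbmspatial.proximity import (
    SpatialNetwork,
    binarize_expression,
    binspect_statistic,
    build_spatial_network,
    expected_pair_counts_complete_graph,
    proximity_enrichment,
)


class TestNetwork:
    def test_unit_square_five_edges(self):
        net = build_spatial_network(
            np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), 10
        )
        assert net.n_edges == 5

    def test_cutoff_below_min_distance_empty(self):
        pts = np.random.default_rng(0).uniform(0, 100, (20, 2))
        net = build_spatial_network(pts, 1e-6)
        assert net.n_edges == 0

    def test_no_self_loops_no_duplicates_and_cutoff(self):
        pts = np.random.default_rng(1).uniform(0, 100, (100, 2))
        net = build_spatial_network(pts, 30)
        assert (net.edges[:, 0] < net.edges[:, 1]).all()
        assert len(np.unique(net.edges, axis=0)) == net.n_edges
        lengths = np.linalg.norm(pts[net.edges[:, 0]] - pts[net.edges[:, 1]], axis=1)
        assert (lengths <= 30).all()

    def test_delaunay_empty_circumcircle_property(self):
        """Independent geometric oracle: every triangulation edge belongs to
        a triangle whose circumcircle is empty of other points."""
        from scipy.spatial import Delaunay

        pts = np.random.default_rng(2).uniform(0, 100, (60, 2))
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            a, b, c = pts[simplex]
            # circumcenter via perpendicular bisector solve
            A = 2 * np.array([b - a, c - a])
            rhs = np.array([b @ b - a @ a, c @ c - a @ a])
            center = np.linalg.solve(A, rhs)
            r = np.linalg.norm(a - center)
            d = np.linalg.norm(pts - center, axis=1)
            others = np.setdiff1d(np.arange(len(pts)), simplex)
            assert (d[others] >= r - 1e-8).all()
        # our network edges are exactly the triangulation's edges (no cutoff)
        expect = set()
        for s in tri.simplices:
            for i in range(3):
                e = (min(s[i], s[(i + 1) % 3]), max(s[i], s[(i + 1) % 3]))
                expect.add(e)
        net = build_spatial_network(pts, np.inf)
        assert set(map(tuple, net.edges)) == expect

    def test_collinear_fallback(self):
        pts = np.column_stack([np.arange(10.0), np.zeros(10)])
        net = build_spatial_network(pts, 2.0)
        assert net.n_edges > 0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            build_spatial_network(np.zeros((2, 2)), 10)


def _complete_network(pts):
    n = len(pts)
    edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
    return SpatialNetwork(np.asarray(pts, float), edges)


class TestEnrichment:
    def test_complete_graph_matches_hypergeometric_closed_form(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (30, 2))
        labels = ["A"] * 12 + ["B"] * 10 + ["C"] * 8
        net = _complete_network(pts)
        res = proximity_enrichment(net, labels, 500, seed=1)
        closed = expected_pair_counts_complete_graph(labels)
        merged = res.merge(closed, on=["type_a", "type_b"], suffixes=("", "_cf"))
        # pair counts on a complete graph are permutation-invariant, so the
        # simulation mean equals the closed form exactly
        assert np.allclose(merged["expected"], merged["expected_cf"])
        assert np.allclose(merged["observed"], merged["expected_cf"])

    def test_four_node_analytic_example(self):
        net = _complete_network(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float))
        res = proximity_enrichment(net, ["A", "A", "B", "B"], 200, seed=0)
        ab = res[(res.type_a == "A") & (res.type_b == "B")]
        assert ab["expected"].iloc[0] == pytest.approx(4.0)

    def test_pair_counts_conserve_edges(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 300, (150, 2))
        net = build_spatial_network(pts, 60)
        labels = rng.choice(["A", "B", "C"], 150)
        res = proximity_enrichment(net, labels, 99, seed=2)
        assert res["observed"].sum() == net.n_edges
        assert res["expected"].sum() == pytest.approx(net.n_edges)

    def test_symmetry_under_label_swap(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 300, (100, 2))
        net = build_spatial_network(pts, 80)
        labels = rng.choice(["A", "B"], 100)
        r1 = proximity_enrichment(net, labels, 99, seed=3)
        swapped = np.where(labels == "A", "B", "A")
        r2 = proximity_enrichment(net, swapped, 99, seed=3)
        ab1 = r1[(r1.type_a == "A") & (r1.type_b == "B")]["observed"].iloc[0]
        ab2 = r2[(r2.type_a == "A") & (r2.type_b == "B")]["observed"].iloc[0]
        assert ab1 == ab2

    def test_planted_pair_enriched(self, niche_tissue):
        cells = niche_tissue["cells"]
        net = build_spatial_network(cells[["x", "y"]].to_numpy(), 50)
        res = proximity_enrichment(net, cells["true_type"], 199, seed=0)
        pair = res[
            (res.type_a == "Fibroblast") & (res.type_b == "PVM")
        ]
        assert pair["log2_enrichment"].iloc[0] > 0
        assert pair["p"].iloc[0] < 0.01

    def test_monotone_power_in_attraction_strength(self):
        """Stronger co-ring mixing of a pair -> larger enrichment."""
        from gbmspatial.synthetic import NicheLayout, Vessel, NICHE_CELL_TYPES, simulate_niche_tissue

        K = len(NICHE_CELL_TYPES)
        enrich = []
        for mix in (0.1, 0.3, 0.5):
            comp = np.full(K, (1 - 2 * mix) / (K - 2))
            comp[NICHE_CELL_TYPES.index("PVM")] = mix
            comp[NICHE_CELL_TYPES.index("Fibroblast")] = mix
            layout = NicheLayout(
                width=900, height=900, density=0.002,
                vessels=[Vessel((450, 450), [250], [list(comp)])],
            )
            cells, _, _ = simulate_niche_tissue(layout, seed=4)
            net = build_spatial_network(cells[["x", "y"]].to_numpy(), 60)
            res = proximity_enrichment(net, cells["true_type"], 99, seed=4)
            pair = res[(res.type_a == "Fibroblast") & (res.type_b == "PVM")]
            enrich.append(pair["log2_enrichment"].iloc[0])
        assert enrich[0] < enrich[1] < enrich[2]

    def test_single_type_raises(self):
        net = _complete_network(np.random.random((5, 2)))
        with pytest.raises(ValueError):
            proximity_enrichment(net, ["A"] * 5, 100)


class TestBinarize:
    def test_separated_modes(self):
        out = binarize_expression(np.array([0, 0, 0, 10, 12, 11]))
        assert out.tolist() == [0, 0, 0, 1, 1, 1]

    def test_constant_gene_raises(self):
        with pytest.raises(ValueError):
            binarize_expression(np.full(10, 3))

    def test_bimodal_mixture_recovered(self):
        rng = np.random.default_rng(0)
        comp = rng.integers(0, 2, 1000)
        counts = np.where(
            comp == 1, rng.negative_binomial(20, 0.5, 1000),
            rng.negative_binomial(1, 0.8, 1000),
        )
        out = binarize_expression(counts)
        assert (out == comp).mean() >= 0.95

    def test_rank_method(self):
        v = np.arange(100)
        out = binarize_expression(v, method="rank", rank_fraction=0.3)
        assert out.sum() == 30


class TestBinspect:
    def test_clique_of_highs_coherent(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 3, (30, 2)), rng.normal(100, 3, (70, 2))])
        net = build_spatial_network(pts, 30)
        binary = np.array([1] * 30 + [0] * 70)
        odds, p = binspect_statistic(net, binary)
        assert odds == np.inf or odds > 10
        assert p < 0.01

    def test_checkerboard_anticoherent(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        pts = np.column_stack([xs.ravel(), ys.ravel()])
        binary = ((xs + ys) % 2).ravel().astype(int)
        net = build_spatial_network(pts, 1.05)
        odds, p = binspect_statistic(net, binary)
        assert odds < 1
        assert p < 0.01

    def test_permutation_variant_calibrated(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 800, (600, 2))
        net = build_spatial_network(pts, 60)
        ps = []
        for g in range(100):
            b = (rng.random(600) < 0.3).astype(int)
            _, p = binspect_statistic(
                net, b, method="permutation", n_permutations=199, seed=g
            )
            ps.append(p)
        fpr = (np.asarray(ps) < 0.05).mean()
        assert 0.0 <= fpr <= 0.08

    def test_degenerate_state_raises(self):
        net = _complete_network(np.random.random((5, 2)))
        with pytest.raises(ValueError):
            binspect_statistic(net, np.ones(5, int))
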