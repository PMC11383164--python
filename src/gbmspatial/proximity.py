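"""Spatial networks, cell-cell proximity enrichment, and binarised spatial
gene-expression coherence.

The spatial network is the Delaunay triangulation of cell centroids with a
maximum edge length; proximity enrichment compares the observed number of
edges joining each unordered pair of cell types with its expectation under
label reshuffling (the network fixed, the type multiset preserved).  The
binarised statistic asks whether cells with high expression of a gene are
adjacent to each other more often than their frequencies predict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay, cKDTree
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


@dataclass
class SpatialNetwork:
    coords: np.ndarray  # (n, 2)
    edges: np.ndarray  # (E, 2) sorted node indices, unique, no self-loops

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_spatial_network(
    coords: np.ndarray, max_edge_length: float = 50.0
) -> SpatialNetwork:
    """Delaunay triangulation with edges above the length cutoff removed.

    Degenerate inputs (collinear points) fall back to a k = 6 nearest-
    neighbour graph under the same cutoff.
    """
    pts = np.asarray(coords, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a spatial network")
    try:
        tri = Delaunay(pts)
        e = set()
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                e.add((min(i, j), max(i, j)))
        edges = np.array(sorted(e), dtype=int)
    except Exception:
        k = min(6, len(pts) - 1)
        tree = cKDTree(pts)
        _, idx = tree.query(pts, k=k + 1)
        e = set()
        for i in range(len(pts)):
            for j in idx[i, 1:]:
                e.add((min(i, int(j)), max(i, int(j))))
        edges = np.array(sorted(e), dtype=int)

    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    edges = edges[lengths <= max_edge_length]
    return SpatialNetwork(coords=pts, edges=edges)


def expected_pair_counts_complete_graph(labels) -> pd.DataFrame:
    """Closed-form expected pair counts under reshuffling on a complete graph.

    For n nodes with n_a of type a: E[count(a,b)] = |E| * 2 n_a n_b / (n(n-1))
    for a != b and |E| * n_a (n_a - 1) / (n(n-1)) for a == b.
    """
    lab = pd.Series(labels)
    n = len(lab)
    n_edges = n * (n - 1) // 2
    counts = lab.value_counts()
    rows = []
    types = sorted(counts.index)
    for i, a in enumerate(types):
        for b in types[i:]:
            if a == b:
                exp = n_edges * counts[a] * (counts[a] - 1) / (n * (n - 1))
            else:
                exp = n_edges * 2 * counts[a] * counts[b] / (n * (n - 1))
            rows.append({"type_a": a, "type_b": b, "expected": float(exp)})
    return pd.DataFrame(rows)


def _pair_counts(edge_codes_a, edge_codes_b, n_types: int) -> np.ndarray:
    lo = np.minimum(edge_codes_a, edge_codes_b)
    hi = np.maximum(edge_codes_a, edge_codes_b)
    return np.bincount(lo * n_types + hi, minlength=n_types * n_types)


def proximity_enrichment(
    network: SpatialNetwork,
    type_labels,
    n_simulations: int = 1000,
    seed: int = 0,
    adjust: bool = True,
) -> pd.DataFrame:
    """Observed vs reshuffled-label expected adjacency per type pair.

    Each simulation permutes the type labels over nodes with the network
    fixed.  Reports log2((observed+1)/(expected+1)), the raw ratio, and an
    add-one-corrected two-sided permutation p based on the deviation of the
    pair count from its simulation mean.
    """
    labels = pd.Series(type_labels).reset_index(drop=True)
    if labels.nunique() < 2:
        raise ValueError("need at least two cell types")
    if n_simulations < 99:
        raise ValueError("use at least 99 simulations")
    rng = np.random.default_rng(seed)
    types = sorted(labels.unique())
    T = len(types)
    code = labels.map({t: i for i, t in enumerate(types)}).to_numpy()
    e0, e1 = network.edges[:, 0], network.edges[:, 1]

    observed = _pair_counts(code[e0], code[e1], T)
    sims = np.empty((n_simulations, T * T), dtype=int)
    for s in range(n_simulations):
        perm = rng.permutation(code)
        sims[s] = _pair_counts(perm[e0], perm[e1], T)

    expected = sims.mean(axis=0)
    dev_obs = np.abs(observed - expected)
    dev_sim = np.abs(sims - expected)
    p = (1.0 + (dev_sim >= dev_obs).sum(axis=0)) / (1.0 + n_simulations)

    rows = []
    for i, a in enumerate(types):
        for j in range(i, T):
            k = i * T + j
            rows.append(
                {
                    "type_a": a,
                    "type_b": types[j],
                    "observed": int(observed[k]),
                    "expected": float(expected[k]),
                    "log2_enrichment": float(
                        np.log2((observed[k] + 1.0) / (expected[k] + 1.0))
                    ),
                    "ratio": float(observed[k] / expected[k])
                    if expected[k] > 0
                    else np.inf,
                    "p": float(p[k]),
                    "n_simulations": n_simulations,
                }
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def binarize_expression(
    gene_counts, method: str = "kmeans", rank_fraction: float = 0.3, seed: int = 0
) -> np.ndarray:
    """Split one gene's counts into high (1) / low (0) cells.

    Default: 2-cluster 1-D k-means on log1p counts, higher-mean cluster is
    high.  ``method="rank"`` marks the top ``rank_fraction`` of cells.
    Constant genes raise (callers should flag and skip).
    """
    v = np.asarray(gene_counts, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError("constant gene cannot be binarised")
    if method == "kmeans":
        lv = np.log1p(v)[:, None]
        km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(lv)
        high = km.cluster_centers_.ravel().argmax()
        return (km.labels_ == high).astype(int)
    if method == "rank":
        cut = np.quantile(v, 1.0 - rank_fraction)
        return (v > cut).astype(int)
    raise ValueError(f"unknown binarisation method {method!r}")


def binspect_statistic(
    network: SpatialNetwork,
    binary: np.ndarray,
    method: str = "fisher",
    n_permutations: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Spatial coherence of a binarised gene: high-high adjacency odds.

    The odds ratio comes from the directed-edge endpoint-state contingency
    table [[2*hh, mixed], [mixed, 2*ll]]: OR > 1 means high cells are
    adjacent to each other more often than endpoint frequencies predict
    (spatially coherent expression); OR < 1 means anti-coherence; OR is inf
    when there are no mixed edges.

    ``method="fisher"`` returns the Fisher exact p of that table (the
    convention of spatial-transcriptomics toolkits; anticonservative because
    edges share endpoints).  ``method="permutation"`` returns an
    add-one-corrected two-sided label-permutation p on the high-high count,
    which is calibrated under the null.
    """
    b = np.asarray(binary).astype(int)
    if b.min() == b.max():
        raise ValueError("both binary states must be present")
    s0 = b[network.edges[:, 0]]
    s1 = b[network.edges[:, 1]]
    hh = int(((s0 == 1) & (s1 == 1)).sum())
    ll = int(((s0 == 0) & (s1 == 0)).sum())
    mixed = int((s0 != s1).sum())
    odds = float("inf") if mixed == 0 else (4.0 * hh * ll) / (mixed * mixed)

    if method == "fisher":
        table = np.array([[2 * hh, mixed], [mixed, 2 * ll]])
        return float(odds), float(stats.fisher_exact(table)[1])
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    e0, e1 = network.edges[:, 0], network.edges[:, 1]
    sims = np.empty(n_permutations, dtype=int)
    for s in range(n_permutations):
        bp = rng.permutation(b)
        sims[s] = np.count_nonzero(bp[e0] & bp[e1])
    mean = sims.mean()
    p = (1.0 + (np.abs(sims - mean) >= abs(hh - mean)).sum()) / (1.0 + n_permutations)
    return float(odds), float(p)
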