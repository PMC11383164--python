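"""Spatial-transcriptomics preprocessing, cell typing, and niche detection.

The pipeline mirrors a standard targeted-panel workflow: filter cells by
detected features, library-size + log normalisation, PCA -> shared
nearest-neighbour graph -> Leiden for expression clusters, then spatial
niches: each cell is described by the cell-type composition of its k = 30
nearest spatial neighbours and cells with similar neighbourhoods are grouped
by k-means into spatial niches (7 in the source analysis).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests


def filter_cells(
    counts: pd.DataFrame, min_features: int = 5, expr_threshold: int = 1
) -> pd.DataFrame:
    """Keep cells with >= min_features genes detected at >= expr_threshold.

    ``counts`` is genes x cells.  Both bounds are inclusive.
    """
    detected = (counts >= expr_threshold).sum(axis=0)
    keep = detected >= min_features
    if not keep.any():
        raise ValueError("no cells pass the feature filter")
    return counts.loc[:, keep]


def normalize_expression(
    counts: pd.DataFrame, mode: str = "lognorm", target_sum: float | None = None
) -> pd.DataFrame:
    """Library-size normalise then log1p; optional per-gene z-scaling.

    ``mode="lognorm"`` scales each cell to the target library size (median
    library by default) and applies log1p — zeros stay zero and cell order
    is preserved.  ``mode="zscore"`` additionally standardises each gene
    (for heatmap display).
    """
    libs = counts.sum(axis=0).astype(float)
    if (libs == 0).any():
        raise ValueError("zero-library cell: filter before normalising")
    target = float(np.median(libs)) if target_sum is None else float(target_sum)
    norm = np.log1p(counts * (target / libs))
    if mode == "lognorm":
        return norm
    if mode == "zscore":
        mu = norm.mean(axis=1)
        sd = norm.std(axis=1)
        sd = sd.where(sd > 1e-12, 1.0)  # constant genes map to 0, not 0/0
        return norm.sub(mu, axis=0).div(sd, axis=0)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def cluster_cell_types(
    normalized: pd.DataFrame,
    resolution: float = 1.0,
    seed: int = 0,
    n_pcs: int = 30,
    n_neighbors: int = 15,
) -> tuple[pd.Series, pd.DataFrame]:
    """Leiden clustering of cells plus per-cluster marker genes.

    ``normalized`` is genes x cells (log-normalised).  Returns
    ``(labels, markers)`` where markers holds Wilcoxon rank-sum tests of
    each cluster vs the rest with Benjamini-Hochberg adjusted p-values.
    """
    if normalized.shape[1] < 2:
        raise ValueError("need at least two cells")
    X = normalized.T  # cells x genes for scanpy
    if float(X.to_numpy().std()) == 0:
        raise ValueError("constant expression matrix cannot be clustered")
    adata = AnnData(
        X.to_numpy(dtype=np.float32),
        obs=pd.DataFrame(index=X.index.astype(str)),
        var=pd.DataFrame(index=X.columns.astype(str)),
    )
    sc.pp.pca(adata, n_comps=min(n_pcs, adata.n_obs - 1, adata.n_vars - 1),
              random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(n_neighbors, adata.n_obs - 1),
                    random_state=seed)
    sc.tl.leiden(
        adata, resolution=resolution, random_state=seed,
        flavor="leidenalg", n_iterations=-1,
    )
    labels = pd.Series(
        adata.obs["leiden"].astype(str).to_numpy(), index=X.index, name="cell_type"
    )

    sc.tl.rank_genes_groups(adata, "leiden", method="wilcoxon")
    frames = []
    for grp in adata.obs["leiden"].cat.categories:
        df = sc.get.rank_genes_groups_df(adata, group=grp)
        df.insert(0, "cluster", grp)
        frames.append(df)
    markers = pd.concat(frames, ignore_index=True)
    markers["p_adj"] = multipletests(
        markers["pvals"].fillna(1.0), method="fdr_bh"
    )[1]
    return labels, markers


def neighborhood_composition(
    coords: np.ndarray, type_labels, k: int = 30
) -> pd.DataFrame:
    """Cell-type counts among each cell's k nearest spatial neighbours.

    Exact Euclidean kNN, self excluded, distance ties broken by cell index.
    Rows sum to k.
    """
    pts = np.asarray(coords, dtype=float)
    labels = pd.Series(type_labels).reset_index(drop=True)
    n = len(pts)
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    types = sorted(labels.unique())
    code = labels.map({t: i for i, t in enumerate(types)}).to_numpy()

    # query extra neighbours, then re-order deterministically by (dist, id)
    extra = min(n - 1, k + 5)
    nn = NearestNeighbors(n_neighbors=extra + 1).fit(pts)
    dist, idx = nn.kneighbors(pts)
    comp = np.zeros((n, len(types)), dtype=int)
    for i in range(n):
        d, j = dist[i], idx[i]
        not_self = j != i
        d, j = d[not_self], j[not_self]
        order = np.lexsort((j, np.round(d, 9)))
        chosen = j[order[:k]]
        comp[i] = np.bincount(code[chosen], minlength=len(types))
    return pd.DataFrame(comp, columns=types)


def kmeans_niches(
    composition: pd.DataFrame,
    n_niches: int = 7,
    seed: int = 0,
    as_frequency: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Group cells with similar neighbourhoods into spatial niches.

    K-means (k-means++ init) on the kNN composition vectors (raw counts by
    default; ``as_frequency`` divides by k).  Returns
    ``(niche labels 1..n, niche x type mean-composition summary)``.
    """
    X = composition.to_numpy(dtype=float)
    if len(X) < n_niches:
        raise ValueError("fewer cells than requested niches")
    if as_frequency:
        X = X / X.sum(axis=1, keepdims=True)
    km = KMeans(n_clusters=n_niches, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(X) + 1
    summary = (
        pd.DataFrame(X, columns=composition.columns)
        .assign(niche=labels)
        .groupby("niche")
        .mean()
    )
    return labels, summary


def niche_type_outliers(
    niche_type_counts: pd.DataFrame, alpha: float = 0.001
) -> pd.DataFrame:
    """Flag cell types over-represented in a niche.

    One-sided binomial test per (niche, type): observed count in the niche
    vs expectation from the global type frequency.  Flags combinations with
    p < alpha and observed > expected.
    """
    tab = niche_type_counts.astype(int)
    total = tab.to_numpy().sum()
    global_freq = tab.sum(axis=0) / total
    rows = []
    for niche in tab.index:
        n_niche = int(tab.loc[niche].sum())
        for t in tab.columns:
            obs = int(tab.loc[niche, t])
            p_exp = float(global_freq[t])
            expected = n_niche * p_exp
            if p_exp in (0.0, 1.0):
                pval = 1.0
            else:
                pval = stats.binomtest(
                    obs, n_niche, p_exp, alternative="greater"
                ).pvalue
            rows.append(
                {
                    "niche": niche,
                    "cell_type": t,
                    "observed": obs,
                    "expected": expected,
                    "p": float(pval),
                    "flagged": bool(pval < alpha and obs > expected),
                }
            )
    return pd.DataFrame(rows)
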