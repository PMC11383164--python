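"""Proximity-based neighborhood features and clustering.

Each cell is described by its Euclidean distance to the nearest cell of
every class present in the FOV (own class uses the nearest *other* cell).
Classes absent from an FOV get the FOV diagonal as a flagged sentinel.
Feature matrices feed k-means (optionally after a t-SNE embedding), with
silhouette-based selection of k when not fixed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score


def jitter_coincident(
    points: np.ndarray, magnitude: float = 0.5, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Displace exactly-coincident points by uniform noise <= magnitude/axis.

    Distinct points are left untouched; jitter is re-drawn (for the moved
    points only) until no duplicates remain.
    """
    if magnitude <= 0:
        raise ValueError("jitter magnitude must be positive")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    pts = np.asarray(points, dtype=float).copy()
    for _ in range(100):
        _, inverse, counts = np.unique(
            pts, axis=0, return_inverse=True, return_counts=True
        )
        dup = counts[inverse] > 1
        if not dup.any():
            return pts
        pts[dup] += rng.uniform(-magnitude, magnitude, size=(int(dup.sum()), pts.shape[1]))
    raise RuntimeError("could not resolve coincident points")


def build_neighborhood_features(
    cells: pd.DataFrame,
    class_col: str = "phenotype_class",
    classes: list[str] | None = None,
    fov_size: tuple[float, float] | None = None,
    jitter_magnitude: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell nearest-neighbour distance to each class within one FOV.

    Returns ``(features, missing_flags)``: features is cells x classes with
    exact nearest distances; missing classes carry the FOV diagonal and are
    flagged True in ``missing_flags``.
    """
    if len(cells) < 2:
        raise ValueError("need at least two cells for neighborhood features")
    pts = jitter_coincident(
        cells[["x", "y"]].to_numpy(float), jitter_magnitude, seed
    )
    labels = cells[class_col].to_numpy()
    if classes is None:
        classes = sorted(pd.unique(labels[pd.notna(labels)]))
    if fov_size is None:
        diag = float(np.hypot(np.ptp(pts[:, 0]), np.ptp(pts[:, 1])))
    else:
        diag = float(np.hypot(*fov_size))

    feats = np.full((len(cells), len(classes)), diag)
    missing = np.zeros((len(cells), len(classes)), dtype=bool)
    for j, cls in enumerate(classes):
        sel = labels == cls
        if not sel.any():
            missing[:, j] = True
            continue
        tree = cKDTree(pts[sel])
        d1, _ = tree.query(pts, k=1)
        feats[:, j] = d1
        # own-class distance must use the nearest *other* cell
        if sel.sum() >= 2:
            d2, _ = tree.query(pts[sel], k=2)
            feats[sel, j] = d2[:, 1]
        else:
            feats[sel, j] = diag
            missing[sel, j] = True
    index = cells.index
    return (
        pd.DataFrame(feats, index=index, columns=classes),
        pd.DataFrame(missing, index=index, columns=classes),
    )


def cluster_groups(
    features: pd.DataFrame | np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    embed: str | None = None,
    k_range: tuple[int, int] = (2, 10),
) -> tuple[np.ndarray, int]:
    """K-means over (optionally t-SNE embedded) feature rows.

    ``k="auto"`` selects the cluster count in ``k_range`` by silhouette
    score.  Returns (labels, k used).  Rows pooled from both timepoints are
    labeled jointly; split the labels afterwards for differential
    composition.
    """
    X = np.asarray(features, dtype=float)
    if embed == "tsne":
        X = TSNE(
            n_components=2, random_state=seed, perplexity=min(30.0, max(5.0, len(X) / 4))
        ).fit_transform(X)
    elif embed is not None:
        raise ValueError(f"unknown embedding {embed!r}")

    if k == 1:
        return np.zeros(len(X), dtype=int), 1
    if k == "auto":
        best = (None, -np.inf, 0)
        for kk in range(k_range[0], min(k_range[1], len(X) - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=10, random_state=seed).fit(X)
            score = silhouette_score(X, km.labels_)
            if score > best[1]:
                best = (km.labels_, score, kk)
        return best[0], best[2]
    k = int(k)
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of rows {len(X)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    return km.labels_, k
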