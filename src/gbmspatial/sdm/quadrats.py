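"""Quadrat counting of classified cell tables and train/val/test splitting.

Quadrats are square grid cells with half-open bounds
[x0, x0+w) x [y0, y0+w); partial edge quadrats are dropped, and a cell
sitting exactly on a shared edge belongs to the quadrat on its right/below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: the 12 model input categories: seven amplification genotypes, the TERTp
#: mutants, the three microenvironment phenotypes, and an all-tumor aggregate
SDM_CATEGORIES: tuple[str, ...] = (
    "CDK4-only",
    "EGFR-only",
    "PDGFRA-only",
    "CDK4/EGFR",
    "CDK4/PDGFRA",
    "EGFR/PDGFRA",
    "triple",
    "TERTp-mutant",
    "immune",
    "endothelial",
    "EC-mimicry",
    "all-tumor",
)

QUADRAT_WIDTHS: tuple[int, ...] = (114, 199, 266, 399)


@dataclass
class QuadratGrid:
    """Regular square tiling of one FOV, origin at (0, 0)."""

    fov_width: float
    fov_height: float
    width: float = 199.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("quadrat width must be positive")
        if self.fov_width < self.width or self.fov_height < self.width:
            raise ValueError("FOV smaller than one quadrat")

    @property
    def nx(self) -> int:
        return int(self.fov_width // self.width)

    @property
    def ny(self) -> int:
        return int(self.fov_height // self.width)

    def assign(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Quadrat indices per cell; -1 marks cells in dropped edge regions."""
        qx = np.floor(np.asarray(x) / self.width).astype(int)
        qy = np.floor(np.asarray(y) / self.width).astype(int)
        out = (qx < 0) | (qx >= self.nx) | (qy < 0) | (qy >= self.ny)
        qx[out] = -1
        qy[out] = -1
        return qx, qy


def cell_sdm_category(classified: pd.DataFrame) -> pd.Series:
    """Map classified cells to their SDM count category (NaN = uncounted).

    EC-mimicry tumor cells count as EC-mimicry; other tumor cells count
    under their amplification genotype, or as TERTp-mutant when their only
    tumor marker is the mutation; immune and endothelial map directly;
    unclassified and excluded cells are not counted (density only).  The
    all-tumor aggregate is added at counting time, not per cell.
    """
    cat = pd.Series(np.nan, index=classified.index, dtype=object)
    ok = ~classified["excluded"].astype(bool)
    phen = classified["phenotype_class"]
    geno = classified["genotype_class"]
    mut = classified["mutation_class"]
    cat[ok & (phen == "immune")] = "immune"
    cat[ok & (phen == "endothelial")] = "endothelial"
    cat[ok & (phen == "EC-mimicry tumor")] = "EC-mimicry"
    tumor = ok & (phen == "tumor")
    cat[tumor & (geno != "none")] = geno[tumor & (geno != "none")]
    cat[tumor & (geno == "none") & (mut == "MUT")] = "TERTp-mutant"
    return cat


def quadrat_count(
    cells: pd.DataFrame,
    grid: QuadratGrid,
    annotation: pd.DataFrame | np.ndarray,
    texture_classes: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Count the 12 categories per quadrat of one FOV and attach labels.

    ``annotation`` is either a per-quadrat label table with columns
    ``qx, qy, texture`` (CSV mode) or a 2-D label mask (pixel array, mask
    mode) whose value at the quadrat center becomes the label.  Quadrats
    without a label are dropped with a warning.
    """
    qx, qy = grid.assign(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    cat = cell_sdm_category(cells)
    is_tumor = cells["phenotype_class"].isin(["tumor", "EC-mimicry tumor"]) & ~cells[
        "excluded"
    ].astype(bool)

    rows = []
    for iy in range(grid.ny):
        for ix in range(grid.nx):
            in_q = (qx == ix) & (qy == iy)
            counts = {
                c: int(((cat == c) & in_q).sum()) for c in SDM_CATEGORIES[:-1]
            }
            counts["all-tumor"] = int((is_tumor.to_numpy() & in_q).sum())
            rows.append({"qx": ix, "qy": iy, **counts})
    out = pd.DataFrame(rows)

    if isinstance(annotation, pd.DataFrame):
        ann = annotation[["qx", "qy", "texture"]]
        out = out.merge(ann, on=["qx", "qy"], how="left")
    else:
        mask = np.asarray(annotation)
        labels = []
        for _, r in out.iterrows():
            cx = int((r["qx"] + 0.5) * grid.width)
            cy = int((r["qy"] + 0.5) * grid.width)
            if 0 <= cy < mask.shape[0] and 0 <= cx < mask.shape[1]:
                val = mask[cy, cx]
                if texture_classes is not None:
                    val = texture_classes[int(val)]
                labels.append(val)
            else:
                labels.append(None)
        out["texture"] = labels

    unlabeled = out["texture"].isna()
    if unlabeled.any():
        warnings.warn(f"dropping {int(unlabeled.sum())} unlabeled quadrats")
        out = out.loc[~unlabeled].reset_index(drop=True)
    return out


def quadrat_dataset(
    classified: pd.DataFrame,
    quadrat_labels: pd.DataFrame,
    quadrat_width: float = 199.0,
    fov_size: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Build the cohort-wide (X, y) quadrat matrix from a classified table.

    Returns ``(X counts, y texture codes, meta)`` with textures coded by
    sorted label order.
    """
    frames = []
    for fov, grp in classified.groupby("fov_id"):
        if fov_size is None:
            ann = quadrat_labels.loc[quadrat_labels["fov_id"] == fov]
            w = quadrat_width
            size = ((ann["qx"].max() + 1) * w, (ann["qy"].max() + 1) * w)
        else:
            size = fov_size
        grid = QuadratGrid(size[0], size[1], quadrat_width)
        ann = quadrat_labels.loc[quadrat_labels["fov_id"] == fov]
        q = quadrat_count(grp, grid, ann)
        q.insert(0, "fov_id", fov)
        frames.append(q)
    data = pd.concat(frames, ignore_index=True)
    X = data[list(SDM_CATEGORIES)].to_numpy(float)
    textures = sorted(data["texture"].unique())
    y = data["texture"].map({t: i for i, t in enumerate(textures)}).to_numpy()
    meta = data[["fov_id", "qx", "qy", "texture"]]
    return X, y, meta


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    constant = span == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s) scaled to 0")
    span[constant] = 1.0
    return (X - lo) / span


def scale_and_split(
    X: np.ndarray,
    y: np.ndarray,
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int | np.random.Generator = 0,
    scale_on_train: bool = False,
) -> dict:
    """Min-max scale then split into train/val/test index sets.

    Scaling is computed on the full data set before splitting (as the source
    procedure specifies; set ``scale_on_train`` to avoid the mild leakage).
    Train size is floor(p_train * n); validation floor(p_val * n); the test
    set takes the remainder.
    """
    if not np.isclose(sum(proportions), 1.0):
        raise ValueError("proportions must sum to 1")
    n = len(X)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    perm = rng.permutation(n)
    n_train = int(np.floor(proportions[0] * n))
    n_val = int(np.floor(proportions[1] * n))
    idx = {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train : n_train + n_val]),
        "test": np.sort(perm[n_train + n_val :]),
    }
    if scale_on_train:
        Xs = np.asarray(X, dtype=float)
        lo = Xs[idx["train"]].min(axis=0)
        span = Xs[idx["train"]].max(axis=0) - lo
        span[span == 0] = 1.0
        Xs = np.clip((Xs - lo) / span, 0.0, 1.0)
    else:
        Xs = minmax_scale(X)
    return {"X": Xs, "y": np.asarray(y), **idx}
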