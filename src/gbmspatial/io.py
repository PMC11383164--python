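"""Readers and writers for the package's plain-text interchange formats.

Cell tables and quadrat labels travel as CSV; expression matrices as an MTX
triplet with ``features.tsv`` / ``cells.tsv`` sidecars; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from scipy import io as spio
from scipy import sparse

CELL_TABLE_COLUMNS = [
    "cell_id",
    "fov_id",
    "x",
    "y",
    "cdk4_spots",
    "egfr_spots",
    "pdgfra_spots",
    "tertp_spots",
    "cd31",
    "cd45ro",
    "hif1a",
]


def write_cell_table(cells: pd.DataFrame, path) -> None:
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing columns: {missing}")
    cells.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table at {path} is missing columns: {missing}")
    return cells


def write_quadrat_labels(quadrats: pd.DataFrame, path) -> None:
    quadrats.to_csv(path, index=False)


def read_quadrat_labels(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_expression_mtx(counts: pd.DataFrame, outdir) -> None:
    """Write a genes x cells count frame as matrix.mtx + features/cells TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(outdir / "matrix.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(
        outdir / "features.tsv", sep="\t", index=False, header=False
    )
    pd.Series(counts.columns).to_csv(
        outdir / "cells.tsv", sep="\t", index=False, header=False
    )


def read_expression_mtx(outdir) -> pd.DataFrame:
    outdir = Path(outdir)
    mat = spio.mmread(outdir / "matrix.mtx").toarray()
    genes = pd.read_csv(outdir / "features.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t", header=None)[0]
    return pd.DataFrame(mat, index=genes, columns=cells)


def write_ground_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_json_dict(), fh)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
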