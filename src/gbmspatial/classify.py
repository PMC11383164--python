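"""Rule-based single-cell genotype, mutation, and phenotype calling.

Input is the tabular output of nuclear segmentation and spot counting:
per-nucleus FISH spot counts for the three oncogenes (*CDK4*, *EGFR*,
*PDGFRA*), a STAR-FISH spot count for the TERT-promoter hotspot mutation,
and binary marker positivity (CD31 endothelial, CD45RO immune, nuclear
HIF1alpha hypoxia).  Classification is deterministic:

* a gene is amplified when its spot count reaches ``amplification_threshold``
  (default 6 copies, analogous to clinical HER2 FISH scoring);
* nuclei with >= ``overlap_threshold`` (default 50) copies of any gene are
  excluded as likely segmentation overlaps;
* any STAR-FISH signal calls the TERTp mutation;
* phenotype precedence: genetically tumor (any amplification or TERTp
  mutation) and CD31-positive -> EC-mimicry tumor; tumor -> tumor;
  CD45RO -> immune; CD31 -> endothelial; otherwise unclassified.
  Nuclear HIF1alpha is an orthogonal "hypoxic" modifier crossed with the
  base phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

GENES: tuple[str, ...] = ("CDK4", "EGFR", "PDGFRA")

#: canonical genotype categories, in display order
GENOTYPE_CLASSES: tuple[str, ...] = (
    "none",
    "CDK4-only",
    "EGFR-only",
    "PDGFRA-only",
    "CDK4/EGFR",
    "CDK4/PDGFRA",
    "EGFR/PDGFRA",
    "triple",
)

PHENOTYPE_CLASSES: tuple[str, ...] = (
    "tumor",
    "immune",
    "endothelial",
    "EC-mimicry tumor",
    "unclassified",
)

MUTATION_CLASSES: tuple[str, ...] = ("WT", "MUT")

_GENOTYPE_BY_SET = {
    frozenset(): "none",
    frozenset({"CDK4"}): "CDK4-only",
    frozenset({"EGFR"}): "EGFR-only",
    frozenset({"PDGFRA"}): "PDGFRA-only",
    frozenset({"CDK4", "EGFR"}): "CDK4/EGFR",
    frozenset({"CDK4", "PDGFRA"}): "CDK4/PDGFRA",
    frozenset({"EGFR", "PDGFRA"}): "EGFR/PDGFRA",
    frozenset({"CDK4", "EGFR", "PDGFRA"}): "triple",
}


@dataclass
class ClassificationScheme:
    """Thresholds and precedence rules for nucleus classification.

    Both thresholds are inclusive ("at least" semantics): a count equal to
    the threshold triggers the call.
    """

    amplification_threshold: int = 6
    overlap_threshold: int = 50
    #: when a genetically non-tumor cell is both CD45RO+ and CD31+, call it
    #: immune (CD45RO is lineage-defining; CD31 can come from adjacent vessel
    #: fragments).  Set False to prefer endothelial.
    immune_over_endothelial: bool = True
    genes: tuple[str, ...] = field(default=GENES)


def assign_genotype(
    spot_counts: dict[str, int], scheme: ClassificationScheme | None = None
) -> tuple[str | None, bool]:
    """Call the amplification genotype from FISH spot counts.

    Returns ``(genotype_class, excluded)``.  ``excluded`` is True when any
    gene reaches the overlap threshold, in which case the genotype is None.
    """
    scheme = scheme or ClassificationScheme()
    amplified = set()
    for gene in scheme.genes:
        if gene not in spot_counts or spot_counts[gene] is None:
            raise ValueError(f"missing spot count for gene {gene!r}")
        count = spot_counts[gene]
        if count < 0 or int(count) != count:
            raise ValueError(f"invalid spot count {count!r} for gene {gene!r}")
        if count >= scheme.overlap_threshold:
            return None, True
        if count >= scheme.amplification_threshold:
            amplified.add(gene)
    return _GENOTYPE_BY_SET[frozenset(amplified)], False


def assign_mutation(tertp_spots: int) -> str:
    """Call TERTp mutation status: any STAR-FISH spot means mutant."""
    if tertp_spots < 0:
        raise ValueError(f"negative STAR-FISH spot count: {tertp_spots}")
    return "MUT" if tertp_spots >= 1 else "WT"


def assign_phenotype(
    markers: dict[str, bool],
    genotype_class: str,
    mutation_class: str,
    scheme: ClassificationScheme | None = None,
) -> tuple[str, bool]:
    """Assign the base phenotype and the hypoxic modifier.

    Returns ``(phenotype_class, hypoxic)``.  A cell is genetically tumor when
    it carries any amplification or the TERTp mutation; tumor cells that are
    CD31-positive are EC-mimicry tumor cells.  Hypoxia (nuclear HIF1alpha) is
    a boolean modifier orthogonal to the base class.
    """
    scheme = scheme or ClassificationScheme()
    cd31 = bool(markers.get("CD31", False))
    cd45ro = bool(markers.get("CD45RO", False))
    hypoxic = bool(markers.get("HIF1A_nuclear", False))

    is_tumor = genotype_class != "none" or mutation_class == "MUT"
    if is_tumor and cd31:
        base = "EC-mimicry tumor"
    elif is_tumor:
        base = "tumor"
    elif cd45ro and cd31:
        base = "immune" if scheme.immune_over_endothelial else "endothelial"
    elif cd45ro:
        base = "immune"
    elif cd31:
        base = "endothelial"
    else:
        base = "unclassified"
    return base, hypoxic


def classify_cells(
    cells: pd.DataFrame, scheme: ClassificationScheme | None = None
) -> pd.DataFrame:
    """Classify a whole cell table (vectorised).

    Expects the columns ``cdk4_spots, egfr_spots, pdgfra_spots, tertp_spots,
    cd31, cd45ro, hif1a``.  Appends ``genotype_class, mutation_class,
    phenotype_class, hypoxic, phenotype_full, excluded``.
    """
    scheme = scheme or ClassificationScheme()
    out = cells.copy()
    counts = np.column_stack(
        [
            out["cdk4_spots"].to_numpy(),
            out["egfr_spots"].to_numpy(),
            out["pdgfra_spots"].to_numpy(),
        ]
    )
    if (counts < 0).any() or out["tertp_spots"].lt(0).any():
        bad = out.index[(counts < 0).any(axis=1) | out["tertp_spots"].lt(0)]
        raise ValueError(f"negative spot counts for cells {list(bad[:5])}")

    excluded = (counts >= scheme.overlap_threshold).any(axis=1)
    amp = counts >= scheme.amplification_threshold

    lut = np.array(
        [
            "none", "PDGFRA-only", "EGFR-only", "EGFR/PDGFRA",
            "CDK4-only", "CDK4/PDGFRA", "CDK4/EGFR", "triple",
        ],
        dtype=object,
    )
    key = amp[:, 0] * 4 + amp[:, 1] * 2 + amp[:, 2]
    genotype = lut[key.astype(int)]
    genotype[excluded] = None

    mutation = np.where(out["tertp_spots"].to_numpy() >= 1, "MUT", "WT")
    cd31 = out["cd31"].astype(bool).to_numpy()
    cd45 = out["cd45ro"].astype(bool).to_numpy()
    hypoxic = out["hif1a"].astype(bool).to_numpy()

    is_tumor = (genotype != "none") & ~excluded | (mutation == "MUT")
    phenotype = np.full(len(out), "unclassified", dtype=object)
    if scheme.immune_over_endothelial:
        phenotype[cd31] = "endothelial"
        phenotype[cd45] = "immune"
    else:
        phenotype[cd45] = "immune"
        phenotype[cd31] = "endothelial"
    phenotype[is_tumor] = "tumor"
    phenotype[is_tumor & cd31] = "EC-mimicry tumor"
    phenotype[excluded] = None

    out["genotype_class"] = genotype
    out["mutation_class"] = mutation
    out["mutation_class"] = out["mutation_class"].where(~excluded, None)
    out["phenotype_class"] = phenotype
    out["hypoxic"] = hypoxic
    out["phenotype_full"] = [
        None if p is None else (f"hypoxic {p}" if h else p)
        for p, h in zip(phenotype, hypoxic)
    ]
    out["excluded"] = excluded
    return out


def qc_lost_nuclei(
    round1_centroids: np.ndarray,
    round2_centroids: np.ndarray,
    match_radius: float = 5.0,
) -> tuple[int, np.ndarray]:
    """Count first-round nuclei lost in a second staining round.

    Greedy nearest-neighbour matching: candidate pairs within
    ``match_radius`` are matched shortest-distance first, each second-round
    centroid used at most once.  Returns ``(n_lost, lost_row_indices)``.
    """
    r1 = np.asarray(round1_centroids, dtype=float)
    r2 = np.asarray(round2_centroids, dtype=float)
    if r1.ndim != 2 or len(r1) == 0:
        raise ValueError("round-1 centroid set is empty")
    if len(r2) == 0:
        return len(r1), np.arange(len(r1))

    tree = cKDTree(r2)
    pairs = tree.query_ball_point(r1, match_radius)
    cand: list[tuple[float, int, int]] = []
    for i, hits in enumerate(pairs):
        for j in hits:
            cand.append((float(np.linalg.norm(r1[i] - r2[j])), i, j))
    cand.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    for _, i, j in cand:
        if i not in used1 and j not in used2:
            used1.add(i)
            used2.add(j)
    lost = np.array([i for i in range(len(r1)) if i not in used1], dtype=int)
    return len(lost), lost
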