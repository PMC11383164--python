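"""Diversity and association statistics over classified cell tables.

Frequency tables per FOV/case/timepoint, Shannon diversity (nats),
co-amplification odds ratios with Haldane-Anscombe correction, Pearson
correlation of per-FOV class frequencies, paired primary-vs-recurrent
Wilcoxon signed-rank tests, and Fisher exact contingency between two FOV
cluster labelings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def shannon_index(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i over categories with p_i > 0.

    Uses natural log (nats), the ecology convention.  Invariant to category
    order and to scaling all counts by a common factor.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no diversity")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def frequency_table(
    cells: pd.DataFrame,
    axis: str = "genotype_class",
    groupby: str | list[str] = "fov_id",
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Per-group counts and proportions of a class axis.

    Excluded cells are always dropped.  Unclassified cells are dropped by
    default (they are only used in spatial analyses for cell density) unless
    ``include_unclassified`` is set.
    """
    df = cells.loc[~cells["excluded"].astype(bool)].copy()
    if axis == "phenotype_class" and not include_unclassified:
        df = df.loc[df[axis] != "unclassified"]
    if axis == "genotype_class" and not include_unclassified:
        # cells with no amplification, no mutation, and no marker are the
        # "unclassified" pool; keep genotype 'none' rows only when the cell
        # is otherwise classified
        mask = (
            (df["genotype_class"] != "none")
            | (df["mutation_class"] == "MUT")
            | (df["phenotype_class"] != "unclassified")
        )
        df = df.loc[mask]
    counts = (
        df.groupby(groupby)[axis].value_counts().rename("count").reset_index()
    )
    counts["proportion"] = counts.groupby(
        groupby if isinstance(groupby, str) else list(groupby)
    )["count"].transform(lambda c: c / c.sum())
    return counts


@dataclass
class OddsRatioResult:
    odds_ratio: float
    log_or: float
    ci_low: float
    ci_high: float
    corrected: bool
    infinite_ci: bool
    table: np.ndarray


def cooccurrence_odds_ratio(
    cells: pd.DataFrame,
    gene_a: str = "EGFR",
    gene_b: str = "CDK4",
    amplification_threshold: int = 6,
) -> OddsRatioResult:
    """Odds ratio for per-cell co-amplification of two genes.

    Builds the 2x2 table of amplified-A x amplified-B cell counts and
    returns OR = (n11*n00)/(n10*n01) with a Haldane-Anscombe +0.5 correction
    when any cell is zero, plus a Wald log-scale 95% CI.
    """
    df = cells.loc[~cells["excluded"].astype(bool)]
    a = df[f"{gene_a.lower()}_spots"].to_numpy() >= amplification_threshold
    b = df[f"{gene_b.lower()}_spots"].to_numpy() >= amplification_threshold
    n11 = int((a & b).sum())
    n10 = int((a & ~b).sum())
    n01 = int((~a & b).sum())
    n00 = int((~a & ~b).sum())
    table = np.array([[n11, n10], [n01, n00]], dtype=float)

    infinite_ci = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    log_or = float(np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0])))
    se = float(np.sqrt((1.0 / t).sum()))
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        log_or=log_or,
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
        corrected=corrected,
        infinite_ci=bool(infinite_ci),
        table=table,
    )


def odds_ratio_from_counts(n11, n10, n01, n00) -> float:
    """OR from raw 2x2 counts, +0.5 corrected when any cell is zero."""
    t = np.array([[n11, n10], [n01, n00]], dtype=float)
    if (t == 0).any():
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def classify_or_groups(
    per_tumor_or: pd.Series | dict, threshold: float | None = None
) -> tuple[pd.Series, float]:
    """Split tumors into OR-high / OR-low groups.

    Default threshold is the cohort median; values strictly above go high,
    ties go low.  An explicit ``threshold`` overrides the median split.
    Returns (labels, threshold used).
    """
    ors = pd.Series(per_tumor_or, dtype=float)
    if threshold is None:
        if len(ors) < 2:
            raise ValueError("median split needs at least two tumors")
        threshold = float(ors.median())
    labels = pd.Series(
        np.where(ors > threshold, "OR_high", "OR_low"), index=ors.index
    )
    return labels, float(threshold)


def correlate_frequencies(freq: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of per-FOV class frequencies.

    ``freq`` is FOVs x categories.  Returns (r matrix, p matrix); constant
    columns yield NaN (flagged as undefined).
    """
    if len(freq) < 3:
        raise ValueError("need at least 3 FOVs for correlation")
    cols = freq.columns
    r = pd.DataFrame(np.nan, index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for cj in cols[i:]:
            x = freq[ci].to_numpy(float)
            y = freq[cj].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[ci, cj] = r.loc[cj, ci] = res.statistic
            p.loc[ci, cj] = p.loc[cj, ci] = res.pvalue
    return r, p


def paired_timepoint_test(primary, recurrent) -> float:
    """Two-tailed paired Wilcoxon signed-rank p-value (exact for n <= 25).

    Zero differences are dropped (Wilcoxon's original treatment).  Raises
    when fewer than two informative (non-zero) pairs remain.
    """
    x = np.asarray(primary, dtype=float)
    y = np.asarray(recurrent, dtype=float)
    if x.shape != y.shape:
        raise ValueError("primary and recurrent must be matched pairs")
    d = x - y
    nz = d[d != 0]
    if len(nz) < 2:
        raise ValueError("fewer than two non-zero pairs: no information")
    method = "exact" if len(nz) <= 25 else "auto"
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(res.pvalue)


def flag_outliers_mad(values, k: float = 3.5) -> np.ndarray:
    """Flag values outside median +/- k * MAD (scaled to sigma).

    A robust stand-in for regression-based outlier removal before case
    averaging; returns a boolean mask of outliers.
    """
    v = np.asarray(values, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med)) * 1.4826
    if mad == 0:
        return np.zeros(len(v), dtype=bool)
    return np.abs(v - med) > k * mad


def cluster_contingency(
    labels_a, labels_b, adjust: bool = True
) -> pd.DataFrame:
    """Fisher exact association between two clusterings of the same FOVs.

    For every (A-cluster, B-cluster) pair, tests the 2x2 table of FOVs
    in/out of the A-cluster crossed with in/out of the B-cluster, one-sided
    for over-representation (a perfectly aligned pair of k-vs-k clusterings
    scores the hypergeometric point mass 1/C(2k, k)).  Returns a tidy frame
    with raw p and (optionally) Benjamini-Hochberg adjusted p.
    """
    a = pd.Series(labels_a)
    b = pd.Series(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must cover the same FOV set")
    if len(a) < 2 or a.nunique() < 2 or b.nunique() < 2:
        raise ValueError("degenerate labeling: need >=2 FOVs and >=2 labels")
    rows = []
    for ca in sorted(a.unique()):
        for cb in sorted(b.unique()):
            in_a = (a == ca).to_numpy()
            in_b = (b == cb).to_numpy()
            table = [
                [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
                [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
            ]
            _, pval = stats.fisher_exact(table, alternative="greater")
            rows.append(
                {"cluster_a": ca, "cluster_b": cb, "n_overlap": table[0][0], "p": pval}
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def diversity_by_group(
    cells: pd.DataFrame,
    axis: str = "genotype_class",
    groupby: str | list[str] = "fov_id",
    include_unclassified: bool = False,
) -> pd.DataFrame:
    """Shannon index of the class distribution within each group."""
    freq = frequency_table(cells, axis, groupby, include_unclassified)
    keys = groupby if isinstance(groupby, list) else [groupby]
    rows = []
    for name, grp in freq.groupby(keys):
        if not isinstance(name, tuple):
            name = (name,)
        rows.append(dict(zip(keys, name)) | {"shannon": shannon_index(grp["count"])})
    return pd.DataFrame(rows)
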