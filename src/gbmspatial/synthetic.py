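"""Synthetic cohorts with planted, recoverable structure.

Three generators mirror the three experimental data streams:

* ``simulate_fov`` / ``simulate_sdm_dataset`` — IF-FISH cell tables for ~90
  fields of view: per-nucleus spot counts around the true copy number,
  marker flags consistent with the true cell type, and per-quadrat ECM
  texture labels sampled from a planted softmax association between cell
  composition and texture.
* ``simulate_niche_tissue`` — a spatial-transcriptomics tissue with
  concentric niche rings around vessel centers, negative-binomial expression
  counts around a per-type signature, and planted co-localised type pairs.

Every generator is deterministic given its seed and returns a
:class:`GroundTruth` record (true types, true textures, true rings, planted
pairs) that downstream analyses never consume — it exists only so tests can
score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: the 12 generative cell-type categories of the imaging cohort
CELL_TYPES: tuple[str, ...] = (
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
    "unclassified",
)

TEXTURES: tuple[str, ...] = ("string-like", "spotty", "mossy")

#: cell types of the spatial-transcriptomics tissue (10 expression clusters)
NICHE_CELL_TYPES: tuple[str, ...] = (
    "EC",
    "Fibroblast",
    "PVM",
    "MAC",
    "Immune",
    "MES",
    "AC-like",
    "OPC-like",
    "NPC-like",
    "Glial",
)

_AMPLIFIED_GENES = {
    "CDK4-only": ("CDK4",),
    "EGFR-only": ("EGFR",),
    "PDGFRA-only": ("PDGFRA",),
    "CDK4/EGFR": ("CDK4", "EGFR"),
    "CDK4/PDGFRA": ("CDK4", "PDGFRA"),
    "EGFR/PDGFRA": ("EGFR", "PDGFRA"),
    "triple": ("CDK4", "EGFR", "PDGFRA"),
    "EC-mimicry": ("EGFR",),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic imaging cohort.

    Defaults emulate the source study's scale: 9 matched cases at 5 FOVs per
    timepoint gives 90 FOVs; a 995 x 597 px FOV tiles into 15 quadrats of
    199 px, giving ~1,300 quadrats cohort-wide; FOVs carry 50-500 cells.
    """

    n_fovs: int = 90
    fov_width: float = 995.0
    fov_height: float = 597.0
    cells_per_fov: int | tuple[int, int] = (150, 400)
    class_frequencies: np.ndarray | None = None  # defaults to uniform over 12
    copy_noise: float = 1.0  # variance multiplier: var = copy_noise * true copies
    normal_copies: int = 2
    amplified_mean: float = 12.0
    hypoxia_rate: float = 0.15
    quadrat_width: float = 199.0
    #: per-quadrat Dirichlet concentration; alpha_i = dispersion * K * p_i.
    #: Small values give strongly clumped compositions (real tissue is patchy).
    composition_dispersion: float = 0.5
    texture_weights: np.ndarray | None = None  # (3 textures x 12 types)
    texture_intercepts: np.ndarray | None = None  # (3,)
    nb_dispersion: float = 0.5  # shared NB dispersion for expression counts
    seed: int = 0

    def frequencies(self) -> np.ndarray:
        p = (
            np.full(len(CELL_TYPES), 1.0 / len(CELL_TYPES))
            if self.class_frequencies is None
            else np.asarray(self.class_frequencies, dtype=float)
        )
        if len(p) != len(CELL_TYPES):
            raise ValueError(f"class_frequencies must have length {len(CELL_TYPES)}")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("class_frequencies must sum to 1")
        return p


@dataclass
class GroundTruth:
    """Planted truth; persisted alongside tables, never consumed by analyses."""

    cell_types: pd.Series | None = None
    quadrat_textures: pd.DataFrame | None = None
    texture_probabilities: np.ndarray | None = None
    niche_ids: pd.Series | None = None
    attraction_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out: dict = {"attraction_pairs": [list(p) for p in self.attraction_pairs]}
        if self.cell_types is not None:
            out["cell_types"] = self.cell_types.tolist()
        if self.niche_ids is not None:
            out["niche_ids"] = self.niche_ids.tolist()
        if self.quadrat_textures is not None:
            out["quadrat_textures"] = self.quadrat_textures.to_dict("list")
        return out


def simulate_spot_counts(true_copies: int, copy_noise: float, rng) -> int:
    """Draw one spot count around a true copy number.

    The noise family has mean ``true_copies`` and variance
    ``copy_noise * true_copies``: 0 is noiseless, 1 is Poisson, values above
    1 are gamma-Poisson (negative binomial) overdispersion, and values in
    (0, 1) mix the exact value with a Poisson draw.
    """
    if copy_noise < 0:
        raise ValueError("copy_noise must be non-negative")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    if copy_noise == 0 or true_copies == 0:
        return int(round(true_copies))
    if copy_noise == 1.0:
        return int(rng.poisson(true_copies))
    if copy_noise < 1.0:
        if rng.random() < copy_noise:
            return int(rng.poisson(true_copies))
        return int(round(true_copies))
    shape = true_copies / (copy_noise - 1.0)
    lam = rng.gamma(shape, copy_noise - 1.0)
    return int(rng.poisson(lam))


def _spot_counts_vector(true_copies: np.ndarray, copy_noise: float, rng) -> np.ndarray:
    """Vectorised version of :func:`simulate_spot_counts`."""
    t = np.asarray(true_copies, dtype=float)
    if copy_noise == 0:
        return np.round(t).astype(int)
    if copy_noise == 1.0:
        return rng.poisson(t)
    out = np.zeros(t.shape, dtype=int)
    nz = t > 0
    if copy_noise < 1.0:
        pois = rng.poisson(t)
        use = rng.random(t.shape) < copy_noise
        out = np.where(use, pois, np.round(t).astype(int))
    else:
        shape = np.where(nz, t / (copy_noise - 1.0), 1.0)
        lam = rng.gamma(shape, copy_noise - 1.0)
        out = np.where(nz, rng.poisson(lam), 0)
    return out


def _observables(types: np.ndarray, config: SimulationConfig, rng) -> pd.DataFrame:
    """Spot counts and marker flags consistent with true cell types."""
    n = len(types)
    cols: dict[str, np.ndarray] = {}
    for gene in ("CDK4", "EGFR", "PDGFRA"):
        true = np.full(n, float(config.normal_copies))
        for t, genes in _AMPLIFIED_GENES.items():
            if gene in genes:
                true[types == t] = config.amplified_mean
        cols[f"{gene.lower()}_spots"] = _spot_counts_vector(true, config.copy_noise, rng)
    # STAR-FISH: mutants always show signal (>=1 spot); others none
    tertp = np.zeros(n, dtype=int)
    mut = types == "TERTp-mutant"
    tertp[mut] = 1 + rng.poisson(1.0, mut.sum())
    cols["tertp_spots"] = tertp
    cols["cd31"] = np.isin(types, ["endothelial", "EC-mimicry"]).astype(int)
    cols["cd45ro"] = (types == "immune").astype(int)
    cols["hif1a"] = (rng.random(n) < config.hypoxia_rate).astype(int)
    return pd.DataFrame(cols)


def simulate_fov(
    config: SimulationConfig,
    seed: int | np.random.Generator,
    fov_id: str = "fov_0",
    composition: str = "global",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one FOV's cell table.

    ``composition="global"`` draws every cell's type from
    ``class_frequencies``; ``"quadrat"`` first draws a Dirichlet composition
    per quadrat of the texture grid, producing the patchy spatial structure
    that the ECM texture model feeds on.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    if isinstance(config.cells_per_fov, tuple):
        lo, hi = config.cells_per_fov
        n = int(rng.integers(lo, hi + 1))
    else:
        n = int(config.cells_per_fov)
    if n <= 0:
        raise ValueError("cells_per_fov must be positive")
    p = config.frequencies()

    x = rng.uniform(0, config.fov_width, n)
    y = rng.uniform(0, config.fov_height, n)
    if composition == "global":
        types = rng.choice(CELL_TYPES, size=n, p=p)
    elif composition == "quadrat":
        w = config.quadrat_width
        nqx = max(int(config.fov_width // w), 1)
        nqy = max(int(config.fov_height // w), 1)
        alpha = config.composition_dispersion * len(CELL_TYPES) * p
        comp = rng.dirichlet(alpha, size=(nqy, nqx))
        qx = np.minimum((x // w).astype(int), nqx - 1)
        qy = np.minimum((y // w).astype(int), nqy - 1)
        types = np.empty(n, dtype=object)
        for iy in range(nqy):
            for ix in range(nqx):
                sel = (qx == ix) & (qy == iy)
                m = int(sel.sum())
                if m:
                    types[sel] = rng.choice(CELL_TYPES, size=m, p=comp[iy, ix])
        types = types.astype(str)
    else:
        raise ValueError(f"unknown composition mode {composition!r}")

    df = _observables(np.asarray(types), config, rng)
    df.insert(0, "y", y)
    df.insert(0, "x", x)
    df.insert(0, "fov_id", fov_id)
    df.insert(0, "cell_id", [f"{fov_id}_c{i}" for i in range(n)])
    truth = GroundTruth(cell_types=pd.Series(types, name="true_type"))
    return df, truth


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def minmax_scale_counts(counts: np.ndarray) -> np.ndarray:
    """Per-feature min-max scaling to [0, 1]; constant features map to 0."""
    c = np.asarray(counts, dtype=float)
    lo = c.min(axis=0)
    span = c.max(axis=0) - lo
    span[span == 0] = 1.0
    return (c - lo) / span


def plant_texture_labels(
    quadrat_counts: np.ndarray,
    weights: np.ndarray,
    intercepts: np.ndarray,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a texture label per quadrat from a softmax in the cell counts.

    Labels are drawn from ``softmax(W @ scaled_counts + b)`` where the counts
    are min-max scaled per feature over the full matrix — the same scale the
    downstream texture classifier consumes, so the planted weights are
    interpretable on the model's input scale.  Returns (labels, probs).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    counts = np.asarray(quadrat_counts, dtype=float)
    W = np.asarray(weights, dtype=float)
    b = np.asarray(intercepts, dtype=float)
    if W.shape != (len(TEXTURES), counts.shape[1]):
        raise ValueError(
            f"weights must be ({len(TEXTURES)} x {counts.shape[1]}), got {W.shape}"
        )
    scaled = minmax_scale_counts(counts)
    probs = softmax(scaled @ W.T + b, axis=1)
    cum = probs.cumsum(axis=1)
    u = rng.random(len(probs))[:, None]
    labels = (u >= cum).sum(axis=1)
    return labels, probs


def planted_texture_weights(
    planted_type: str = "CDK4-only",
    planted_texture: str = "string-like",
    strength: float = 60.0,
    support_strength: float = 36.0,
    support_types: tuple[str, str] = ("immune", "endothelial"),
) -> tuple[np.ndarray, np.ndarray]:
    """A weight matrix with one dominant planted (type -> texture) pair.

    The two remaining textures each get a weaker association with a support
    type so that all three classes are learnable; the planted pair keeps the
    strictly largest weight and is the one recovery tests score.
    """
    W = np.zeros((len(TEXTURES), len(CELL_TYPES)))
    ti = TEXTURES.index(planted_texture)
    W[ti, CELL_TYPES.index(planted_type)] = strength
    others = [i for i in range(len(TEXTURES)) if i != ti]
    for k, tex in enumerate(others):
        W[tex, CELL_TYPES.index(support_types[k])] = support_strength
    b = np.zeros(len(TEXTURES))
    return W, b


def simulate_sdm_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the full imaging cohort for the texture model.

    Returns ``(cells, quadrat_labels, truth)``; ``quadrat_labels`` has one
    row per full quadrat (fov_id, qx, qy, texture) sampled from the planted
    association between true-type quadrat counts and texture.  Texture
    weights default to :func:`planted_texture_weights`.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if config.texture_weights is None:
        W, b = planted_texture_weights()
    else:
        W = np.asarray(config.texture_weights, dtype=float)
        b = (
            np.zeros(len(TEXTURES))
            if config.texture_intercepts is None
            else np.asarray(config.texture_intercepts, dtype=float)
        )

    frames = []
    truths = []
    for f in range(config.n_fovs):
        df, truth = simulate_fov(config, rng, fov_id=f"fov_{f}", composition="quadrat")
        frames.append(df)
        truths.append(truth.cell_types)
    cells = pd.concat(frames, ignore_index=True)
    true_types = pd.concat(truths, ignore_index=True)

    # quadrat counts over the true types (generator side; the analysis side
    # recomputes its own counts from the classified table)
    w = config.quadrat_width
    nqx = int(config.fov_width // w)
    nqy = int(config.fov_height // w)
    rows = []
    counts = []
    for f in range(config.n_fovs):
        fov = f"fov_{f}"
        sel = cells["fov_id"] == fov
        x = cells.loc[sel, "x"].to_numpy()
        y = cells.loc[sel, "y"].to_numpy()
        t = true_types[sel.to_numpy()].to_numpy()
        qx = (x // w).astype(int)
        qy = (y // w).astype(int)
        for iy in range(nqy):
            for ix in range(nqx):
                in_q = (qx == ix) & (qy == iy)
                vec = [
                    int(((t == ct) & in_q).sum()) for ct in CELL_TYPES
                ]
                rows.append({"fov_id": fov, "qx": ix, "qy": iy})
                counts.append(vec)
    count_mat = np.array(counts, dtype=float)
    labels, probs = plant_texture_labels(count_mat, W, b, rng)
    quadrats = pd.DataFrame(rows)
    quadrats["texture"] = [TEXTURES[k] for k in labels]

    truth = GroundTruth(
        cell_types=true_types,
        quadrat_textures=quadrats.copy(),
        texture_probabilities=probs,
    )
    return cells, quadrats, truth


# ---------------------------------------------------------------------------
# spatial-transcriptomics tissue
# ---------------------------------------------------------------------------


@dataclass
class Vessel:
    """One vessel with concentric rings of distinct composition.

    ``radii`` are strictly increasing outer radii; ``ring_compositions`` is
    one probability vector over cell types per ring.
    """

    center: tuple[float, float]
    radii: Sequence[float]
    ring_compositions: Sequence[Sequence[float]]

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if (np.diff(r) <= 0).any() or (r <= 0).any():
            raise ValueError("vessel radii must be positive and strictly increasing")
        if len(self.ring_compositions) != len(r):
            raise ValueError("one composition vector per ring is required")
        for comp in self.ring_compositions:
            c = np.asarray(comp, dtype=float)
            if not np.isclose(c.sum(), 1.0) or (c < 0).any():
                raise ValueError("ring compositions must be probability vectors")


@dataclass
class NicheLayout:
    width: float = 1500.0
    height: float = 1500.0
    vessels: list[Vessel] = field(default_factory=list)
    background_composition: np.ndarray | None = None
    density: float = 0.003  # cells per px^2, uniform across rings + background
    cell_types: tuple[str, ...] = NICHE_CELL_TYPES


def default_niche_layout() -> NicheLayout:
    """One central vessel with three rings, emulating the perivascular
    organisation seen in recurrent tumors: a vascular core (ECs +
    fibroblasts), a perivascular-macrophage ring, and an outer
    mesenchymal/OPC shell.  The planted attraction pairs are (EC, Fibroblast)
    and (PVM, Fibroblast)."""
    K = len(NICHE_CELL_TYPES)

    def comp(**kv: float) -> list[float]:
        c = np.zeros(K)
        for name, v in kv.items():
            c[NICHE_CELL_TYPES.index(name.replace("_", "-"))] = v
        return list(c / c.sum())

    vessel = Vessel(
        center=(750.0, 750.0),
        radii=[150.0, 300.0, 450.0],
        ring_compositions=[
            comp(EC=0.5, Fibroblast=0.4, Glial=0.1),
            comp(PVM=0.45, Fibroblast=0.35, Immune=0.1, Glial=0.1),
            comp(MES=0.6, **{"OPC_like": 0.3}, Glial=0.1),
        ],
    )
    background = comp(
        **{"AC_like": 0.25, "NPC_like": 0.2, "OPC_like": 0.1},
        MAC=0.15, Immune=0.1, Glial=0.15, MES=0.05,
    )
    return NicheLayout(vessels=[vessel], background_composition=np.asarray(background))


def default_signature(
    cell_types: Sequence[str] = NICHE_CELL_TYPES,
    markers_per_type: int = 6,
    marker_mean: float = 8.0,
    baseline_mean: float = 0.2,
    n_background_genes: int = 10,
) -> pd.DataFrame:
    """Mean expression per gene per type: block-diagonal marker panel.

    Each type gets ``markers_per_type`` private markers at ``marker_mean``
    counts; everything else sits at ``baseline_mean``; a tail of background
    genes is expressed at mean 1 everywhere.  Scale emulates a targeted
    in-situ panel with on the order of 100 transcripts per cell.
    """
    genes = []
    rows = []
    for t in cell_types:
        for m in range(markers_per_type):
            genes.append(f"{t}_mk{m}")
            rows.append(
                [marker_mean if u == t else baseline_mean for u in cell_types]
            )
    for g in range(n_background_genes):
        genes.append(f"bg{g}")
        rows.append([1.0] * len(cell_types))
    return pd.DataFrame(rows, index=genes, columns=list(cell_types))


def simulate_niche_tissue(
    layout: NicheLayout | None = None,
    signature: pd.DataFrame | None = None,
    nb_dispersion: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a spatial-transcriptomics tissue with concentric niches.

    Cells are placed uniformly at ``layout.density``; a cell inside ring k of
    a vessel draws its type from that ring's composition, otherwise from the
    background.  Expression counts are negative binomial with the signature
    mean and a shared dispersion (var = mu + dispersion * mu^2).

    Returns ``(cells, counts, truth)`` where ``cells`` has cell_id/x/y/
    true_type, ``counts`` is genes x cells, and ``truth.niche_ids`` holds the
    ring index per cell (0 = background, then 1.. per ring outward, offset
    per vessel).
    """
    rng = np.random.default_rng(seed)
    layout = layout or default_niche_layout()
    signature = signature if signature is not None else default_signature(layout.cell_types)
    types_list = list(layout.cell_types)

    centers = np.array([v.center for v in layout.vessels], dtype=float)
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            min_sep = layout.vessels[i].radii[-1] + layout.vessels[j].radii[-1]
            if np.linalg.norm(centers[i] - centers[j]) < min_sep:
                import warnings

                warnings.warn("vessel outer radii overlap; rings will mix")

    n = rng.poisson(layout.density * layout.width * layout.height)
    x = rng.uniform(0, layout.width, n)
    y = rng.uniform(0, layout.height, n)

    ring_id = np.zeros(n, dtype=int)
    offset = 0
    for v in layout.vessels:
        d = np.hypot(x - v.center[0], y - v.center[1])
        prev = 0.0
        for k, r in enumerate(v.radii):
            sel = (d >= prev) & (d < r) & (ring_id == 0)
            ring_id[sel] = offset + k + 1
            prev = r
        offset += len(v.radii)

    bg = (
        np.asarray(layout.background_composition, dtype=float)
        if layout.background_composition is not None
        else np.full(len(types_list), 1.0 / len(types_list))
    )
    types = np.empty(n, dtype=object)
    types[ring_id == 0] = rng.choice(types_list, size=int((ring_id == 0).sum()), p=bg)
    offset = 0
    for v in layout.vessels:
        for k in range(len(v.radii)):
            sel = ring_id == offset + k + 1
            comp = np.asarray(v.ring_compositions[k], dtype=float)
            types[sel] = rng.choice(types_list, size=int(sel.sum()), p=comp)
        offset += len(v.radii)

    mu = signature[types].to_numpy(dtype=float)  # genes x cells
    if nb_dispersion > 0:
        lam = rng.gamma(1.0 / nb_dispersion, nb_dispersion * mu)
    else:
        lam = mu
    counts = rng.poisson(lam)
    counts_df = pd.DataFrame(
        counts, index=signature.index, columns=[f"cell_{i}" for i in range(n)]
    )
    cells = pd.DataFrame(
        {
            "cell_id": counts_df.columns,
            "x": x,
            "y": y,
            "true_type": types.astype(str),
        }
    )
    truth = GroundTruth(
        cell_types=cells["true_type"],
        niche_ids=pd.Series(ring_id, name="true_niche"),
        attraction_pairs=[("EC", "Fibroblast"), ("PVM", "Fibroblast")],
    )
    return cells, counts_df, truth
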