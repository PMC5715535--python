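"""Synthetic fetal-liver single-cell expression data with known ground truth.

The generator emulates the study design this package analyses: six cell
types (hepatoblast, mesenchymal, endothelial, erythrocyte, macrophage,
megakaryocyte) sampled across ordered developmental stages with
stage-varying proportions, a panel of marker genes per type, hepatoblast
trajectory genes with monotone stage trends, 92 ERCC-like spike-in control
rows, and a per-gene technical-noise law CV^2 = a1/mu + a0 realised as a
gamma compound with logistic drop-out in mu.

All randomness flows from a single integer seed; identical configurations
produce bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SPIKEIN_PREFIX

CELL_TYPES = (
    "hepatoblast",
    "mesenchymal",
    "endothelial",
    "erythrocyte",
    "macrophage",
    "megakaryocyte",
)

DEFAULT_STAGES = ("E11.5", "E12.5", "E13.5", "E14.5", "E16.5", "E18.5", "P2.5")

# Literature marker panels; these ids are reused by the cell-typing module.
PANEL_GENES = {
    "hepatoblast": ["Afp", "Alb", "Hnf4a", "Krt18", "Krt8", "Gpc3", "Dlk1"],
    "mesenchymal": ["Vim", "Col1a2", "Mest", "Mmp2", "Pdgfra", "Ncam1", "Lhx2"],
    "endothelial": ["Lyve1", "Kdr"],
    "erythrocyte": ["Hba-a1", "Hbb-bt"],
    "macrophage": ["Ptprc", "Cd68", "Cd52"],
    "megakaryocyte": ["Itga2b", "Itgb3"],
}

# Extra named hepatoblast markers: isolation-marker candidates assessed in
# the marker module (several are membrane receptors).
EXTRA_TYPE_GENES = {
    "hepatoblast": ["Cdh1", "Anpep", "Prom1", "Gcgr", "Cdhr2", "Lgr5", "Cd24a", "Igdcc4"],
    "erythrocyte": ["Hba-a2", "Hbb-bs", "Alas2", "Slc4a1"],
}

# Cholangiocyte-specific genes: silent in all six fetal-liver types,
# activated only by simulate_cholangiocytes.
CHOLANGIOCYTE_GENES = ["Sox9", "Spp1", "Krt7", "Krt19", "Epcam", "Hes1"]

# Primary lineage markers in fetal liver are strongly expressed (Afp/Alb
# reach thousands of FPKM; hemoglobins and platelet genes even more so,
# which also keeps rare-type markers visible in population averages);
# secondary isolation-marker candidates sit at a moderate level.  Most of
# the transcriptome is non-differential, with a long right tail of strongly
# expressed housekeeping-like genes.
MARKER_HIGH_FPKM = {
    "hepatoblast": 1000.0,
    "mesenchymal": 1500.0,
    "endothelial": 2000.0,
    "erythrocyte": 2000.0,
    "macrophage": 1000.0,
    "megakaryocyte": 3000.0,
}
MARKER_MID_FPKM = 120.0
MARKER_LOW_FPKM = 0.1
SILENT_FPKM = 0.05
TRAJ_OFF_FPKM = 0.2
# trajectory genes span per-gene starting levels of 1..64 FPKM
TRAJ_BASE_LOG2_RANGE = (0.0, 6.0)


def _default_proportions(stages) -> dict:
    """Per-stage simplex over the six types.

    Hepatoblasts expand and mesenchymal cells decrease stepwise across
    development; erythroid cells shrink as haematopoiesis relocates.
    """
    start = np.array([0.28, 0.24, 0.10, 0.22, 0.11, 0.05])
    end = np.array([0.50, 0.04, 0.10, 0.12, 0.19, 0.05])
    n = len(stages)
    out = {}
    for i, st in enumerate(stages):
        t = i / max(n - 1, 1)
        vec = (1 - t) * start + t * end
        out[st] = dict(zip(CELL_TYPES, vec / vec.sum()))
    return out


@dataclass
class SimConfig:
    """Generator settings; defaults are the study conditions emulated.

    noise_a0 is the dimensionless CV^2 floor, noise_a1 the FPKM-scaled
    shot-noise slope; drop-out probability falls logistically with ln(mu)
    around dropout_midpoint (FPKM). trajectory_effect is in log2-fold units
    per stage step.
    """

    n_genes: int = 2000
    n_spikeins: int = 92
    stages: tuple = DEFAULT_STAGES
    cells_per_stage: int = 60
    type_proportions: dict = None  # type: ignore[assignment]
    noise_a0: float = 0.05
    noise_a1: float = 4.0
    dropout_midpoint: float = 0.5
    dropout_slope: float = 2.0
    n_trajectory_genes: int = 30
    trajectory_effect: float = 1.0
    n_marker_genes_per_type: int = 15
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if self.type_proportions is None:
            self.type_proportions = _default_proportions(self.stages)
        for cnt, name in [
            (self.n_genes, "n_genes"),
            (self.n_spikeins, "n_spikeins"),
            (self.cells_per_stage, "cells_per_stage"),
            (self.n_trajectory_genes, "n_trajectory_genes"),
            (self.n_marker_genes_per_type, "n_marker_genes_per_type"),
        ]:
            if cnt <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_a0 < 0 or self.noise_a1 < 0:
            raise ValueError("noise constants must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        for st in self.stages:
            props = self.type_proportions[st]
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"type proportions for stage {st} sum to {total}, not 1"
                )


@dataclass
class GroundTruth:
    """Generating truth: per-cell type/stage/outlier, per-gene role/trend."""

    cells: pd.DataFrame  # index cell id: type, stage, outlier
    genes: pd.DataFrame  # index gene id: role, trend, marker_type
    noise_a0: float = 0.0
    noise_a1: float = 0.0

    def to_tsv(self, cells_path: str, genes_path: str) -> None:
        self.cells.to_csv(cells_path, sep="\t")
        self.genes.to_csv(genes_path, sep="\t")


def _gene_roles(config: SimConfig) -> pd.DataFrame:
    """Assign each biological gene exactly one role."""
    rows: list[tuple[str, str, str, str, str]] = []  # id, role, trend, type, tier
    seen: set[str] = set()

    def add(gid: str, role: str, trend: str = "none", mtype: str = "", tier: str = "") -> None:
        if gid in seen:
            raise ValueError(f"overlapping gene-role assignment for {gid!r}")
        seen.add(gid)
        rows.append((gid, role, trend, mtype, tier))

    for ctype in CELL_TYPES:
        panel = PANEL_GENES[ctype]
        named = panel + EXTRA_TYPE_GENES.get(ctype, [])
        fillers = [
            f"{ctype.capitalize()}Mk{i:02d}"
            for i in range(1, config.n_marker_genes_per_type - len(named) + 1)
        ]
        for gid in (named + fillers)[: config.n_marker_genes_per_type]:
            add(gid, "marker", mtype=ctype, tier="high" if gid in panel else "mid")
    n_up = config.n_trajectory_genes // 2
    up_named = ["Apoh", "Ahsg"]
    down_named = ["Mdk"]
    for i in range(n_up):
        gid = up_named[i] if i < len(up_named) else f"TrajUp{i + 1:02d}"
        add(gid, "trajectory", trend="up")
    for i in range(config.n_trajectory_genes - n_up):
        gid = down_named[i] if i < len(down_named) else f"TrajDn{i + 1:02d}"
        add(gid, "trajectory", trend="down")
    for gid in CHOLANGIOCYTE_GENES:
        add(gid, "chol_marker")
    n_neutral = config.n_genes - len(rows)
    if n_neutral < 0:
        raise ValueError("n_genes too small for the requested marker/trajectory genes")
    for i in range(n_neutral):
        add(f"Gene{i + 1:05d}", "neutral")
    df = pd.DataFrame(rows, columns=["gene", "role", "trend", "marker_type", "tier"])
    return df.set_index("gene")


def _mean_table(config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene baseline mean plus role metadata; stage handling downstream."""
    n = len(genes)
    base = 10.0 ** rng.uniform(-0.3, 3.0, size=n)  # ~0.5 .. 1000 FPKM
    traj = genes["role"].to_numpy() == "trajectory"
    base[traj] = 2.0 ** rng.uniform(*TRAJ_BASE_LOG2_RANGE, size=traj.sum())
    tab = genes.copy()
    tab["base_mean"] = base
    return tab


def _gene_means_for(config: SimConfig, tab: pd.DataFrame, ctype: str, stage_idx: int) -> np.ndarray:
    """Expected FPKM per gene for one (cell type, stage)."""
    n_stage = len(config.stages)
    mu = np.empty(len(tab))
    role = tab["role"].to_numpy()
    trend = tab["trend"].to_numpy()
    mtype = tab["marker_type"].to_numpy()
    base = tab["base_mean"].to_numpy()

    mu[role == "neutral"] = base[role == "neutral"]
    is_marker = role == "marker"
    tier = tab["tier"].to_numpy()
    own_level = np.where(tier == "high", MARKER_HIGH_FPKM[ctype], MARKER_MID_FPKM)
    mu[is_marker] = np.where(
        mtype[is_marker] == ctype, own_level[is_marker], MARKER_LOW_FPKM
    )
    mu[role == "chol_marker"] = SILENT_FPKM
    is_traj = role == "trajectory"
    if ctype == "hepatoblast":
        up = is_traj & (trend == "up")
        down = is_traj & (trend == "down")
        mu[up] = base[up] * 2.0 ** (stage_idx * config.trajectory_effect)
        mu[down] = base[down] * 2.0 ** ((n_stage - 1 - stage_idx) * config.trajectory_effect)
    else:
        mu[is_traj] = TRAJ_OFF_FPKM
    return mu


def _draw_expression(
    mu: np.ndarray,
    n_cells: int,
    config: SimConfig,
    rng: np.random.Generator,
    dropout: bool = True,
) -> np.ndarray:
    """Gamma-compound draw honouring CV^2 = a1/mu + a0, then drop-out."""
    g = len(mu)
    out = np.tile(mu[:, None], (1, n_cells)).astype(float)
    pos = mu > 0
    cv2 = np.zeros(g)
    cv2[pos] = config.noise_a1 / mu[pos] + config.noise_a0
    noisy = pos & (cv2 > 0)
    if noisy.any():
        shape = 1.0 / cv2[noisy]
        scale = mu[noisy] * cv2[noisy]
        out[noisy, :] = rng.gamma(
            shape[:, None], scale[:, None], size=(noisy.sum(), n_cells)
        )
    if dropout and config.dropout_midpoint > 0:
        logit = config.dropout_slope * (
            np.log(np.maximum(mu, 1e-12)) - np.log(config.dropout_midpoint)
        )
        p_keep = 1.0 / (1.0 + np.exp(-logit))
        keep = rng.random(size=(g, n_cells)) < p_keep[:, None]
        out = np.where(keep, out, 0.0)
    return out


def _spikein_means(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return 10.0 ** rng.uniform(0.0, 3.0, size=config.n_spikeins)


def simulate_fetal_liver(config: SimConfig):
    """Simulate the full fetal-liver design.

    Returns ``(ExpressionMatrix, CellAnnotation, GroundTruth)`` where the
    annotation is a DataFrame indexed by cell id with ``stage``, ``batch``
    and ``sorted_population`` columns.  Spike-in rows share one global mean
    profile across all cells and carry only technical (gamma) noise, no
    drop-out.
    """
    rng = np.random.default_rng([config.seed, 101])
    genes = _gene_roles(config)
    tab = _mean_table(config, genes, rng)
    spike_mu = _spikein_means(config, rng)
    spike_ids = [f"{SPIKEIN_PREFIX}{i + 1:05d}" for i in range(config.n_spikeins)]

    blocks = []
    cell_ids: list[str] = []
    cell_types: list[str] = []
    cell_stages: list[str] = []
    for si, stage in enumerate(config.stages):
        props = config.type_proportions[stage]
        pvec = np.array([props[t] for t in CELL_TYPES])
        counts = rng.multinomial(config.cells_per_stage, pvec)
        for ctype, n in zip(CELL_TYPES, counts):
            if n == 0:
                continue
            mu = _gene_means_for(config, tab, ctype, si)
            bio = _draw_expression(mu, n, config, rng, dropout=True)
            spk = _draw_expression(spike_mu, n, config, rng, dropout=False)
            blocks.append(np.vstack([bio, spk]))
            start = len(cell_ids)
            cell_ids.extend(f"{stage}_c{start + j:04d}" for j in range(n))
            cell_types.extend([ctype] * n)
            cell_stages.extend([stage] * n)

    values = np.hstack(blocks)
    gene_ids = list(tab.index) + spike_ids
    matrix = ExpressionMatrix(pd.DataFrame(values, index=gene_ids, columns=cell_ids))

    annotation = pd.DataFrame(
        {
            "stage": cell_stages,
            "batch": "b1",
            "sorted_population": "",
        },
        index=pd.Index(cell_ids, name="cell"),
    )

    truth_cells = pd.DataFrame(
        {"type": cell_types, "stage": cell_stages, "outlier": False},
        index=pd.Index(cell_ids, name="cell"),
    )
    gene_truth = tab[["role", "trend", "marker_type", "tier"]].copy()
    spike_truth = pd.DataFrame(
        {"role": "spikein", "trend": "none", "marker_type": "", "tier": ""},
        index=pd.Index(spike_ids, name="gene"),
    )
    truth = GroundTruth(
        cells=truth_cells,
        genes=pd.concat([gene_truth, spike_truth]),
        noise_a0=config.noise_a0,
        noise_a1=config.noise_a1,
    )

    if config.outlier_fraction > 0:
        matrix, flags = inject_outliers(
            matrix, config.outlier_fraction, seed=config.seed + 7919
        )
        truth.cells.loc[flags.index[flags], "outlier"] = True
    return matrix, annotation, truth


def simulate_cholangiocytes(config: SimConfig, n_cells: int, base=None):
    """Simulate Epcam-positive cholangiocytes anchored to early hepatoblasts.

    ``base`` is the ``(matrix, annotation, truth)`` triple from a prior
    :func:`simulate_fetal_liver` run; the cholangiocyte expression profile
    is drawn around the earliest-stage hepatoblast centroid with
    cholangiocyte markers activated, hepatoblast-specific markers silenced,
    and heavier drop-out on neutral genes (fewer detected genes per cell).
    """
    if base is None:
        raise ValueError("cholangiocyte simulation requires a prior fetal-liver simulation")
    base_matrix, _, base_truth = base
    rng = np.random.default_rng([config.seed, 202])

    first_stage = config.stages[0]
    hb = base_truth.cells.query("type == 'hepatoblast' and stage == @first_stage")
    if hb.empty:
        raise ValueError("base simulation contains no earliest-stage hepatoblasts")
    centroid = base_matrix.values[list(hb.index)].mean(axis=1)

    gene_ids = list(base_matrix.genes)
    roles = base_truth.genes.loc[gene_ids, "role"].to_numpy()
    mtype = base_truth.genes.loc[gene_ids, "marker_type"].to_numpy()

    mu = centroid.to_numpy().copy()
    mu[roles == "chol_marker"] = 1000.0
    mu[(roles == "marker") & (mtype == "hepatoblast")] = SILENT_FPKM
    mu[(roles == "marker") & (mtype != "hepatoblast")] = MARKER_LOW_FPKM
    spike = roles == "spikein"
    if n_cells == 0:
        empty = pd.DataFrame(index=pd.Index(gene_ids, name="gene"), columns=[], dtype=float)
        annotation = pd.DataFrame(
            columns=["stage", "batch", "sorted_population"], index=pd.Index([], name="cell")
        )
        truth = GroundTruth(
            cells=pd.DataFrame(columns=["type", "stage", "outlier"], index=pd.Index([], name="cell")),
            genes=base_truth.genes.copy(),
            noise_a0=config.noise_a0,
            noise_a1=config.noise_a1,
        )
        return ExpressionMatrix(empty, base_matrix.spikein_mask.copy()), annotation, truth

    bio_idx = ~spike
    vals = np.empty((len(gene_ids), n_cells))
    vals[bio_idx, :] = _draw_expression(mu[bio_idx], n_cells, config, rng, dropout=True)
    vals[spike, :] = _draw_expression(mu[spike], n_cells, config, rng, dropout=False)

    # Differentiated cells detect fewer genes.  The reduction is mostly a
    # shared transcriptional shutdown (the same neutral genes silenced in
    # every cell, keeping cells well correlated with each other) plus a
    # mild extra per-cell drop-out.
    neutral = roles == "neutral"
    silenced = rng.random(neutral.sum()) < 0.35
    sub = vals[neutral, :]
    sub[silenced, :] = 0.0
    extra_keep = rng.random(size=sub.shape) < 0.8
    vals[neutral, :] = np.where(extra_keep, sub, 0.0)

    cell_ids = [f"P3.25_chol_c{i:04d}" for i in range(n_cells)]
    matrix = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=cell_ids),
        base_matrix.spikein_mask.copy(),
    )
    annotation = pd.DataFrame(
        {"stage": "P3.25", "batch": "b2", "sorted_population": "Epcam+"},
        index=pd.Index(cell_ids, name="cell"),
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"type": "cholangiocyte", "stage": "P3.25", "outlier": False},
            index=pd.Index(cell_ids, name="cell"),
        ),
        genes=base_truth.genes.copy(),
        noise_a0=config.noise_a0,
        noise_a1=config.noise_a1,
    )
    return matrix, annotation, truth


def simulate_sorted_population(
    n_typical: int = 35,
    n_atypical: int = 7,
    n_library_outliers: int = 10,
    n_genes: int = 500,
    seed: int = 0,
):
    """Sorted-population (Epcam-positive-like) matrix for two-stage QC.

    Builds three cell classes around one shared expression profile:
    typical cells (small log-normal noise), atypical cells (an unrelated
    profile of the same magnitude, so normal library size but low
    correlation to the population median), and library outliers (the
    shared profile crushed to a tiny detected-gene count).  Returns the
    matrix and a per-cell class Series ("typical" / "atypical" /
    "library_outlier").
    """
    rng = np.random.default_rng([seed, 404])
    base_log = rng.uniform(0.0, 8.0, size=n_genes)

    cols = {}
    classes = {}

    def expr(log_profile, noise_sd):
        v = 2.0 ** (log_profile + rng.normal(0, noise_sd, size=n_genes)) - 1.0
        return np.maximum(v, 0.0)

    for i in range(n_typical):
        cid = f"typ_{i:03d}"
        cols[cid] = expr(base_log, 0.4)
        classes[cid] = "typical"
    for i in range(n_atypical):
        cid = f"atyp_{i:03d}"
        cols[cid] = expr(rng.permutation(base_log), 0.4)
        classes[cid] = "atypical"
    for i in range(n_library_outliers):
        cid = f"out_{i:03d}"
        v = expr(base_log, 0.4) * 0.02
        keep = rng.random(n_genes) < 0.1
        cols[cid] = np.where(keep, v, 0.0)
        classes[cid] = "library_outlier"

    genes = [f"Gene{i + 1:05d}" for i in range(n_genes)]
    matrix = ExpressionMatrix(pd.DataFrame(cols, index=genes))
    return matrix, pd.Series(classes, name="class")


def inject_outliers(matrix: ExpressionMatrix, fraction: float, seed: int = 0):
    """Degrade a random subset of cells to low-quality libraries.

    Selected cells are globally down-scaled and given heavy extra drop-out,
    collapsing their detected-gene counts.  Returns the new matrix and a
    boolean per-cell flag Series.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng([seed, 303])
    n = matrix.n_cells
    n_out = int(np.floor(n * fraction + 0.5))
    flags = pd.Series(False, index=matrix.cells, name="outlier")
    if n_out == 0:
        return ExpressionMatrix(matrix.values.copy(), matrix.spikein_mask.copy()), flags
    chosen = rng.choice(n, size=n_out, replace=False)
    vals = matrix.values.to_numpy().copy()
    for j in chosen:
        col = vals[:, j] * 0.05
        keep = rng.random(len(col)) < 0.25
        vals[:, j] = np.where(keep, col, 0.0)
    flags.iloc[chosen] = True
    new = ExpressionMatrix(
        pd.DataFrame(vals, index=matrix.genes, columns=matrix.cells),
        matrix.spikein_mask.copy(),
    )
    return new, flags
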