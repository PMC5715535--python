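"""Hepatoblast developmental trajectory over ordered stages.

Stage-differential genes are ranked by one-way ANOVA (restricted to genes
detected, FPKM > 1, in at least ``min_cells`` cells), the top genes define
the developmental track, monotone trends are called by Spearman correlation
of stage-mean expression with the stage ordinal, and query cells (e.g.
sorted cholangiocytes) are assigned to their most-correlated stage
centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .celltyping import embed_tsne, oneway_f
from .matrix import ExpressionMatrix


@dataclass
class StageSeries:
    """Ordered stages plus per-gene stage means, ANOVA ranking and trends."""

    stages: list  # ordered stage labels
    stage_means: pd.DataFrame  # genes x stages, log2(FPKM+1) means
    anova: pd.DataFrame  # genes: F, p (eligible genes only)
    top_genes: list
    trends: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def ordinal(self, stage) -> int:
        return self.stages.index(stage)


def stage_anova(
    matrix: ExpressionMatrix,
    stages: pd.Series,
    stage_order: list,
    min_cells: int = 3,
    top_k: int = 30,
    detection_threshold: float = 1.0,
) -> StageSeries:
    """Rank stage-differential genes in a stage-annotated cell population.

    Eligibility: FPKM > ``detection_threshold`` in at least ``min_cells``
    cells.  One-way ANOVA runs on log2(FPKM+1) across the given ordered
    stages; the ``top_k`` genes by F define the trajectory gene set.
    """
    stages = stages.loc[list(matrix.cells)]
    present = [s for s in stage_order if (stages == s).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need at least 2 stages with at least 2 cells each")
    bio = matrix.biological()
    eligible = (bio.values > detection_threshold).sum(axis=1) >= min_cells
    if not eligible.any():
        raise ValueError("no gene is detected in enough cells")
    sub = bio.subset_genes(list(bio.genes[eligible]))
    logv = sub.log2p1()
    groups = [logv[stages.index[stages == s]].to_numpy() for s in present]
    F, p = oneway_f(groups)
    anova = pd.DataFrame({"F": F, "p": p}, index=sub.genes).sort_values(
        ["F"], ascending=False, kind="mergesort"
    )
    order = sorted(range(len(sub.genes)), key=lambda i: (-F[i], str(sub.genes[i])))
    top = [sub.genes[i] for i in order[:top_k]]
    stage_means = pd.DataFrame(
        {s: logv[stages.index[stages == s]].mean(axis=1) for s in present}
    )
    series = StageSeries(stages=present, stage_means=stage_means, anova=anova, top_genes=top)
    series.trends = pd.Series(
        {g: classify_trend(series, g) for g in sub.genes}, name="trend"
    )
    return series


def classify_trend(series: StageSeries, gene: str) -> str:
    """Monotone trend of a gene's stage means: "up", "down" or "none".

    Spearman correlation of stage ordinal vs stage-mean expression;
    "up" at rho >= 0.8, "down" at rho <= -0.8.
    """
    if len(series.stages) < 3:
        warnings.warn("fewer than 3 stages: trend undefined")
        return "none"
    y = series.stage_means.loc[gene].to_numpy(dtype=float)
    if np.all(y == y[0]):
        return "none"
    rho, _ = stats.spearmanr(np.arange(len(y)), y)
    if not np.isfinite(rho):
        return "none"
    if rho >= 0.8:
        return "up"
    if rho <= -0.8:
        return "down"
    return "none"


def build_track(
    matrix: ExpressionMatrix,
    stages: pd.Series,
    series: StageSeries,
    seed: int = 0,
):
    """Hierarchy and 2-D embedding of the trajectory cells on the top genes.

    Returns ``(linkage_matrix, coords)``; with a single stage no track
    ordering is meaningful and the linkage alone describes the population.
    """
    if not series.top_genes:
        raise ValueError("empty trajectory gene set")
    sub = matrix.subset_genes([g for g in series.top_genes if g in matrix.genes])
    X = np.log2(sub.values.to_numpy().T + 1.0)
    if X.std(axis=1).min() == 0:
        X = X.copy()
        X[X.std(axis=1) == 0, 0] += 1e-9
    Z = linkage(pdist(X, metric="correlation"), method="average")
    coords = embed_tsne(matrix, series.top_genes, seed=seed)
    return Z, coords


def stage_centroid_order(coords: pd.DataFrame, stages: pd.Series, stage_order: list) -> list:
    """Order of stages along the first embedding axis of their centroids."""
    cent = coords.groupby(stages.loc[coords.index]).mean()
    present = [s for s in stage_order if s in cent.index]
    ranked = cent.loc[present, "tsne1"].rank().sort_values().index.tolist()
    return ranked


def nearest_stage_assignment(
    query: ExpressionMatrix, series: StageSeries
) -> tuple[pd.DataFrame, dict]:
    """Assign each query cell to the stage centroid it correlates with best.

    Correlation is Pearson on log2(FPKM+1) over the trajectory gene set.
    Returns the per-cell table (stage + per-stage correlations) and a
    summary with the modal stage and per-stage assignment fractions.
    """
    genes = [g for g in series.top_genes if g in query.genes]
    if not genes:
        raise ValueError("no trajectory gene present in the query matrix")
    centroids = series.stage_means.loc[[g for g in genes if g in series.stage_means.index]]
    genes = list(centroids.index)
    logq = np.log2(query.values.loc[genes] + 1.0)

    rows = []
    for cell in query.cells:
        x = logq[cell].to_numpy()
        if x.std() < 1e-12:
            rows.append({"stage": "unassigned", **{s: np.nan for s in series.stages}})
            continue
        cors = {}
        for s in series.stages:
            c = centroids[s].to_numpy()
            cors[s] = np.nan if c.std() < 1e-12 else float(np.corrcoef(x, c)[0, 1])
        best = max(series.stages, key=lambda s: (-np.inf if np.isnan(cors[s]) else cors[s]))
        rows.append({"stage": best, **cors})
    table = pd.DataFrame(rows, index=query.cells)
    assigned = table["stage"][table["stage"] != "unassigned"]
    frac = assigned.value_counts(normalize=True).to_dict() if len(assigned) else {}
    modal = assigned.mode().iloc[0] if len(assigned) else "unassigned"
    summary = {"modal_stage": modal, "fractions": frac, "n_query": int(query.n_cells)}
    return table, summary
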