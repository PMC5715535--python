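"""Marker-free cell-type decomposition and cluster annotation.

Cells are grouped by unsupervised hierarchical clustering (distance
1 - Pearson on log2(FPKM+1), average linkage) over the top genes ranked by
PCA loading, in two passes: a first 2-way cut separates hepatoblasts, then
the remainder is cut into six clusters, clusters whose top-scoring marker
panel coincides are merged (e.g. two macrophage sub-clusters), and each
cluster is labelled by its best marker panel.  Erythrocyte-associated genes
can be excluded from the gene ranking.  Cluster identity is corroborated by
hypergeometric GO-style over-representation with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .matrix import ExpressionMatrix
from .simulate import PANEL_GENES

DEFAULT_EXCLUSION = ["Hba-a2", "Hbb-bs", "Alas2", "Slc4a1"]


@dataclass
class MarkerPanelSet:
    """Named marker-gene panels plus an optional gene exclusion list."""

    panels: dict = field(default_factory=lambda: {k: list(v) for k, v in PANEL_GENES.items()})
    exclusion: list = field(default_factory=lambda: list(DEFAULT_EXCLUSION))

    def __post_init__(self) -> None:
        excl = set(self.exclusion)
        for name, genes in self.panels.items():
            if not genes:
                raise ValueError(f"panel {name!r} is empty")
            overlap = excl & set(genes)
            if overlap:
                raise ValueError(
                    f"panel {name!r} shares genes with the exclusion list: {sorted(overlap)}"
                )

    @classmethod
    def from_config(cls, path: str) -> "MarkerPanelSet":
        """Plain-text config: ``name: gene1,gene2``; ``exclude:`` line optional."""
        panels: dict = {}
        exclusion: list = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, _, genes = line.partition(":")
                ids = [g.strip() for g in genes.split(",") if g.strip()]
                if name.strip().lower() == "exclude":
                    exclusion = ids
                else:
                    panels[name.strip()] = ids
        return cls(panels=panels, exclusion=exclusion)

    def to_config(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, genes in self.panels.items():
                fh.write(f"{name}: {','.join(genes)}\n")
            if self.exclusion:
                fh.write(f"exclude: {','.join(self.exclusion)}\n")


@dataclass
class Clustering:
    """Cluster ids per cell, per-cluster panel scores and type labels."""

    labels: pd.Series  # cell -> cluster id (string)
    linkage_matrix: np.ndarray | None = None
    scores: pd.DataFrame | None = None  # cluster x panel
    types: dict = field(default_factory=dict)  # cluster -> type label
    status: str = "ok"

    def cell_types(self) -> pd.Series:
        """Per-cell assigned type label."""
        return self.labels.map(lambda c: self.types.get(c, "unassigned")).rename("type")

    def n_groups(self) -> int:
        return self.labels.nunique()


def rank_genes_by_pca(
    matrix: ExpressionMatrix,
    k: int = 400,
    exclusion: list | None = None,
    variance_target: float = 0.85,
) -> list[str]:
    """Rank genes by maximum absolute PCA loading.

    PCA is run on log2(FPKM+1) cells-by-genes data (spike-ins and excluded
    genes dropped); a gene's score is its maximum |loading| over the
    leading components that together explain ``variance_target`` of the
    variance.  The top ``k`` gene ids are returned.
    """
    if matrix.n_cells < 2:
        raise ValueError("PCA ranking needs at least 2 cells")
    bio = matrix.biological()
    if exclusion:
        keep = [g for g in bio.genes if g not in set(exclusion)]
        bio = bio.subset_genes(keep)
    X = np.log2(bio.values.to_numpy().T + 1.0)  # cells x genes
    n_comp = min(X.shape) - 1 if min(X.shape) > 1 else 1
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, variance_target) + 1)
    n_keep = min(n_keep, pca.components_.shape[0])
    scores = np.abs(pca.components_[:n_keep]).max(axis=0)
    order = sorted(
        range(len(scores)), key=lambda i: (-round(scores[i], 12), str(bio.genes[i]))
    )
    return [bio.genes[i] for i in order[:k]]


def hierarchical_cluster(
    matrix: ExpressionMatrix, genes: list[str], n_clusters: int
) -> Clustering:
    """Average-linkage clustering with distance 1 - Pearson on log2(FPKM+1).

    Deterministic given its input: cells are processed in lexicographic id
    order and the tree is cut to exactly ``n_clusters``.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be at least 2")
    if matrix.n_cells < n_clusters:
        raise ValueError("fewer cells than requested clusters")
    cells = sorted(matrix.cells, key=str)
    sub = matrix.subset_cells(cells).subset_genes([g for g in genes if g in matrix.genes])
    X = np.log2(sub.values.to_numpy().T + 1.0)  # cells x genes
    sd = X.std(axis=1)
    if np.any(sd == 0):
        # constant cells have undefined correlation; nudge one entry
        X = X.copy()
        X[sd == 0, 0] += 1e-9
    dist = pdist(X, metric="correlation")
    Z = linkage(dist, method="average")
    flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    labels = pd.Series([f"c{v}" for v in flat], index=pd.Index(cells, name="cell"), name="cluster")
    return Clustering(labels=labels.loc[list(matrix.cells)], linkage_matrix=Z)


def annotate_clusters(
    matrix: ExpressionMatrix, clustering: Clustering, panels: MarkerPanelSet
) -> Clustering:
    """Label each cluster by its best-scoring marker panel.

    Panel score = mean, over the panel's genes present in the matrix, of
    the cluster-mean log2(FPKM+1) expression z-scored across clusters.
    An exact top-score tie yields the label "unassigned".
    """
    logv = matrix.log2p1()
    clusters = sorted(clustering.labels.unique())
    cluster_means = pd.DataFrame(
        {c: logv[clustering.labels.index[clustering.labels == c]].mean(axis=1) for c in clusters}
    )
    sd = cluster_means.std(axis=1, ddof=0)
    z = cluster_means.sub(cluster_means.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0)
    z = z.fillna(0.0)

    scores = {}
    for name, genes in panels.panels.items():
        present = [g for g in genes if g in matrix.genes]
        if not present:
            warnings.warn(f"no gene of panel {name!r} present in matrix")
            scores[name] = pd.Series(np.nan, index=clusters)
        else:
            scores[name] = z.loc[present].mean(axis=0)
    score_df = pd.DataFrame(scores)

    types = {}
    for c in clusters:
        row = score_df.loc[c].dropna()
        if row.empty:
            types[c] = "unassigned"
            continue
        best = row.max()
        winners = row.index[row == best]
        types[c] = winners[0] if len(winners) == 1 else "unassigned"
    return Clustering(
        labels=clustering.labels,
        linkage_matrix=clustering.linkage_matrix,
        scores=score_df,
        types=types,
        status=clustering.status,
    )


def two_pass_decomposition(
    matrix: ExpressionMatrix,
    panels: MarkerPanelSet | None = None,
    k_genes: int = 400,
    n_second_pass: int = 6,
) -> Clustering:
    """Two-pass marker-free decomposition with marker-panel merge.

    Pass 1 cuts all cells into 2 groups and labels the hepatoblast-scoring
    group.  Pass 2 re-clusters the remainder into ``n_second_pass`` groups,
    merges clusters whose top-scoring panel coincides, and labels each
    final group.
    """
    panels = panels or MarkerPanelSet()
    if "hepatoblast" not in panels.panels:
        raise ValueError("panels must include a hepatoblast panel")

    genes1 = rank_genes_by_pca(matrix, k_genes, exclusion=panels.exclusion)
    pass1 = annotate_clusters(matrix, hierarchical_cluster(matrix, genes1, 2), panels)

    # hepatoblast group = the cluster actually expressing the hepatoblast
    # panel; if both clusters express it the population is hepatoblast-only
    # (contrast-based z-scores are meaningless without a second type)
    logv = matrix.log2p1()
    hb_genes = [g for g in panels.panels["hepatoblast"] if g in matrix.genes]
    if not hb_genes:
        raise ValueError("no hepatoblast panel gene present in matrix")
    hb_expr = {
        c: logv.loc[hb_genes, pass1.labels.index[pass1.labels == c]].mean().mean()
        for c in pass1.labels.unique()
    }
    hb_cluster = max(hb_expr, key=hb_expr.get)
    hb_cells = pass1.labels.index[pass1.labels == hb_cluster]
    rest_cells = pass1.labels.index[pass1.labels != hb_cluster]

    if min(hb_expr.values()) > 1.0 or len(rest_cells) < n_second_pass:
        labels = pd.Series("hepatoblast", index=matrix.cells, name="cluster")
        cl = Clustering(labels=labels, types={"hepatoblast": "hepatoblast"},
                        status="single-population: second pass skipped")
        return cl

    rest = matrix.subset_cells(list(rest_cells))
    genes2 = rank_genes_by_pca(rest, k_genes, exclusion=panels.exclusion)
    pass2 = annotate_clusters(rest, hierarchical_cluster(rest, genes2, n_second_pass), panels)

    # merge second-pass clusters sharing a top-scoring panel
    merged = pass2.labels.map(lambda c: f"m_{pass2.types[c]}")
    merged_types = {f"m_{t}": t for t in pass2.types.values()}

    labels = pd.concat(
        [
            pd.Series("hepatoblast", index=hb_cells),
            merged,
        ]
    ).loc[list(matrix.cells)]
    labels.name = "cluster"
    labels.index.name = "cell"
    types = {"hepatoblast": "hepatoblast", **merged_types}
    scores = pass2.scores
    return Clustering(labels=labels, linkage_matrix=pass2.linkage_matrix,
                      scores=scores, types=types)


def oneway_f(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA over gene rows.

    ``groups`` is a list of (genes x cells_in_group) arrays.  Returns
    (F, p).  A gene constant everywhere gets F = 0, p = 1; zero
    within-group variance with distinct means gets F = inf, p -> 0.
    """
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups])
    n = ns.sum()
    grand = sum(g.sum(axis=1) for g in groups) / n
    means = [g.mean(axis=1) for g in groups]
    ssb = sum(ni * (m - grand) ** 2 for ni, m in zip(ns, means))
    ssw = sum(((g - m[:, None]) ** 2).sum(axis=1) for g, m in zip(groups, means))
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), F)
    p = stats.f.sf(F, dfb, dfw)
    p = np.where(np.isinf(F), 0.0, np.where(F == 0, 1.0, p))
    return F, p


def anova_rank_display_genes(
    matrix: ExpressionMatrix, labels: pd.Series, k: int = 400
) -> list[str]:
    """Genes ordered by one-way ANOVA F across cell-type labels (log2 scale)."""
    logv = matrix.biological().log2p1()
    counts = labels.value_counts()
    usable = counts.index[counts >= 2]
    dropped = counts.index[counts < 2]
    if len(dropped):
        warnings.warn(f"labels with < 2 cells dropped: {list(dropped)}")
    if len(usable) < 2:
        raise ValueError("need at least 2 labels with >= 2 cells each")
    groups = [logv[labels.index[labels == lab]].to_numpy() for lab in usable]
    F, _ = oneway_f(groups)
    genes = logv.index
    order = sorted(range(len(genes)), key=lambda i: (-F[i], str(genes[i])))
    return [genes[i] for i in order[:k]]


def embed_tsne(
    matrix: ExpressionMatrix, genes: list[str], seed: int = 0, perplexity: float = 30.0
) -> pd.DataFrame:
    """2-D t-SNE embedding of cells on a selected gene set; seed-reproducible."""
    sub = matrix.subset_genes([g for g in genes if g in matrix.genes])
    X = np.log2(sub.values.to_numpy().T + 1.0)
    n = X.shape[0]
    max_perp = max((n - 1) / 3.0, 1.0)
    if perplexity > max_perp:
        warnings.warn(f"perplexity reduced to {max_perp:.1f} for {n} cells")
        perplexity = max_perp
    ts = TSNE(n_components=2, random_state=int(seed), perplexity=perplexity, init="pca")
    coords = ts.fit_transform(X)
    return pd.DataFrame(coords, index=matrix.cells, columns=["tsne1", "tsne2"])


def cell_type_proportions(labels: pd.Series, stages: pd.Series) -> pd.DataFrame:
    """Per-stage cell-type proportions (rows sum to 1)."""
    df = pd.DataFrame({"label": labels, "stage": stages.loc[labels.index]})
    if df["stage"].isna().any():
        raise ValueError("every cell needs a stage")
    tab = pd.crosstab(df["stage"], df["label"])
    if (tab.sum(axis=1) == 0).any():
        raise ValueError("empty stage")
    return tab.div(tab.sum(axis=1), axis=0)


def count_coexpressing_cells(
    matrix: ExpressionMatrix, set_a: list[str], set_b: list[str], threshold: float = 1.0
) -> tuple[int, list[str]]:
    """Cells with at least one gene of each set above the FPKM threshold."""
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    for g in list(set_a) + list(set_b):
        if g not in matrix.genes:
            raise KeyError(f"unknown gene id: {g!r}")
    pos_a = (matrix.values.loc[list(set_a)] > threshold).any(axis=0)
    pos_b = (matrix.values.loc[list(set_b)] > threshold).any(axis=0)
    both = pos_a & pos_b
    return int(both.sum()), list(matrix.cells[both])


def go_overrepresentation(
    query: set, universe: set, annotation: dict
) -> pd.DataFrame:
    """Hypergeometric over-representation with Bonferroni correction.

    Raw p = P(X >= overlap) for overlap of the query with each term's
    universe genes; adjusted p = min(1, p * number of tested terms).
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for term, genes in annotation.items():
        term_genes = set(genes) & universe
        if not term_genes:
            continue
        overlap = len(term_genes & query)
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(term_genes), len(query))
        rows.append((term, overlap, len(term_genes), float(p)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_raw"]).set_index("term")
    m = len(df)
    df["p_adj"] = np.minimum(1.0, df["p_raw"] * m)
    df["significant"] = df["p_adj"] < 0.05
    return df.sort_values(["p_adj", "p_raw"])


def read_gmt(path: str) -> dict:
    """GMT gene-set file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(g for g in parts[2:] if g)
    return out
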