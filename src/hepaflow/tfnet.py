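"""Transcription-factor expression covariance networks.

TFs differentially expressed between two cell groups (two-sided Wilcoxon
rank-sum, raw p < 0.01) are connected by edges where the pairwise Pearson
correlation of log2(FPKM+1) expression exceeds 0.35 (strict), and a TF is
kept as a network node iff it has at least three such partners — the
degree rule is evaluated once on the full thresholded graph, not
iteratively, so degrees inside the final subgraph can drop below three.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


def screen_de_tfs(
    matrix: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    tf_list: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Differentially expressed TFs between two cell groups.

    Two-sided Wilcoxon rank-sum on log2(FPKM+1) per TF; retained iff raw
    p < alpha (the threshold is applied uncorrected).  Direction is the
    sign of the median difference ("a" or "b" = higher group).
    """
    if len(group_a) < 5 or len(group_b) < 5:
        raise ValueError("both groups need at least 5 cells")
    if not tf_list:
        raise ValueError("tf_list must be non-empty")
    logv = matrix.log2p1()
    rows = []
    for tf in tf_list:
        if tf not in matrix.genes:
            warnings.warn(f"TF {tf!r} absent from matrix; skipped")
            continue
        a = logv.loc[tf, list(group_a)].to_numpy()
        b = logv.loc[tf, list(group_b)].to_numpy()
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue
        stat, p = stats.ranksums(a, b)
        direction = "a" if np.median(a) > np.median(b) else "b"
        rows.append((tf, float(stat), float(p), direction, p < alpha))
    df = pd.DataFrame(rows, columns=["tf", "stat", "p", "higher_in", "significant"])
    return df.set_index("tf")


def tf_correlation_matrix(
    matrix: ExpressionMatrix, tfs: list[str], cells: list[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations of TF expression on log2(FPKM+1).

    Diagonal is 1; a zero-variance TF has all off-diagonal entries NaN.
    """
    cells = list(cells) if cells is not None else list(matrix.cells)
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    tfs = list(tfs)
    if len(tfs) < 2:
        raise ValueError("need at least 2 TFs")
    logv = np.log2(matrix.values.loc[tfs, cells].to_numpy() + 1.0)
    sd = logv.std(axis=1)
    n = len(tfs)
    corr = np.full((n, n), np.nan)
    valid = sd > 0
    if valid.sum() >= 2:
        corr[np.ix_(valid, valid)] = np.corrcoef(logv[valid])
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=tfs, columns=tfs)


def build_covariance_network(
    corr: pd.DataFrame, r_min: float = 0.35, min_partners: int = 3
) -> nx.Graph:
    """Threshold graph with a one-shot minimum-partner node rule.

    Edge iff r > r_min strictly; a node is retained iff its degree in that
    full thresholded graph is at least ``min_partners``; the network is the
    induced subgraph on retained nodes (edge weights = r).
    """
    if corr.empty:
        raise ValueError("empty correlation table")
    full = nx.Graph()
    full.add_nodes_from(corr.index)
    tfs = list(corr.index)
    for i, a in enumerate(tfs):
        for b in tfs[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_min:
                full.add_edge(a, b, weight=float(r))
    keep = [n for n in full.nodes if full.degree(n) >= min_partners]
    return full.subgraph(keep).copy()


def hub_ranking(network: nx.Graph) -> list[tuple[str, int]]:
    """TFs by descending partner count within the network, ties alphabetical."""
    return sorted(network.degree, key=lambda kv: (-kv[1], str(kv[0])))


def export_network(network: nx.Graph, path: str, layout_seed: int = 0) -> pd.DataFrame:
    """Write a TSV edge list and return seed-reproducible layout coordinates.

    The layout is force-directed (Fruchterman-Reingold); coordinates are
    written beside the edge list as ``<path>.layout.tsv``.
    """
    edges = pd.DataFrame(
        [(a, b, d["weight"]) for a, b, d in network.edges(data=True)],
        columns=["tf_a", "tf_b", "r"],
    ).sort_values(["tf_a", "tf_b"])
    edges.to_csv(path, sep="\t", index=False)
    pos = nx.spring_layout(network, seed=int(layout_seed))
    coords = pd.DataFrame(
        [(n, xy[0], xy[1]) for n, xy in sorted(pos.items(), key=lambda kv: str(kv[0]))],
        columns=["tf", "x", "y"],
    )
    coords.to_csv(f"{path}.layout.tsv", sep="\t", index=False)
    return coords


def read_network(path: str) -> nx.Graph:
    """Read an edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for _, row in df.iterrows():
        g.add_edge(row["tf_a"], row["tf_b"], weight=float(row["r"]))
    return g


def read_tf_list(path: str) -> list[str]:
    """One gene id per line; blank lines and # comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
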