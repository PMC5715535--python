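"""Isolation-marker performance: sensitivity, specificity and prediction.

For a candidate marker gene, a cell is "positive" when its FPKM exceeds a
detection threshold (default 1, strict).  Against cell-type labels inferred
from the global transcriptome:

* sensitivity  = positive target cells / all target cells
  (do the marker-positive cells include most of the target population?)
* specificity  = positive target cells / all positive cells
  (is the marker-positive pool pure?)  This is positive-pool purity
  (precision); the conventional true-negative rate is reported as an
  extra column ``tnr`` to avoid confusion.

Candidate new markers must clear a sensitivity and specificity cutoff at
every required stage and appear on a membrane-receptor list.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def marker_positive(matrix: ExpressionMatrix, gene: str, threshold: float = 1.0) -> pd.Series:
    """Boolean per cell: FPKM strictly above the threshold."""
    if gene not in matrix.genes:
        raise KeyError(f"unknown gene id: {gene!r}")
    return (matrix.values.loc[gene] > threshold).rename(gene)


def assess_markers(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    stages: pd.Series,
    genes: list[str],
    target_type: str,
    threshold: float = 1.0,
) -> pd.DataFrame:
    """Per (gene, stage) isolation sensitivity and specificity for one type.

    Counts and scores are computed within each stage's cells only.  A stage
    with no target cells has undefined sensitivity; a gene positive in no
    cell of a stage has undefined specificity (both reported as NaN).
    """
    labels = labels.loc[list(matrix.cells)]
    stages = stages.loc[list(matrix.cells)]
    rows = []
    stage_values = list(pd.unique(stages))
    for gene in genes:
        pos = marker_positive(matrix, gene, threshold)
        for st in stage_values:
            in_stage = stages == st
            is_target = labels == target_type
            pos_target = int((pos & in_stage & is_target).sum())
            pos_other = int((pos & in_stage & ~is_target).sum())
            target_total = int((in_stage & is_target).sum())
            pos_total = pos_target + pos_other
            other_total = int((in_stage & ~is_target).sum())
            sens = pos_target / target_total if target_total else np.nan
            spec = pos_target / pos_total if pos_total else np.nan
            tnr = (other_total - pos_other) / other_total if other_total else np.nan
            rows.append(
                (gene, target_type, st, sens, spec, tnr,
                 pos_target, pos_other, target_total, pos_total)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "type", "stage", "sensitivity", "specificity", "tnr",
            "pos_target", "pos_other", "target_total", "pos_total",
        ],
    )


def marker_pair_quadrants(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    cells: list[str] | None = None,
    threshold: float = 1.0,
) -> dict:
    """2x2 co-expression counts for a marker pair over a cell set."""
    cells = list(cells) if cells is not None else list(matrix.cells)
    pos_a = marker_positive(matrix, gene_a, threshold).loc[cells]
    pos_b = marker_positive(matrix, gene_b, threshold).loc[cells]
    return {
        "both": int((pos_a & pos_b).sum()),
        "a_only": int((pos_a & ~pos_b).sum()),
        "b_only": int((~pos_a & pos_b).sum()),
        "neither": int((~pos_a & ~pos_b).sum()),
    }


def predict_markers(
    performance: pd.DataFrame,
    membrane_list: list[str],
    cutoff: float = 0.5,
    required_stages: list | None = None,
    min_stages: int | None = None,
) -> pd.DataFrame:
    """Membrane genes clearing the sensitivity/specificity cutoff per stage.

    A gene qualifies iff sensitivity > cutoff AND specificity > cutoff
    (strict) at every required stage (or at least ``min_stages`` of them
    when given) and it appears on the membrane list.  Output is ordered by
    descending worst-stage min(sens, spec), then alphabetically.
    """
    if not membrane_list:
        warnings.warn("empty membrane list: no candidate can qualify")
        return pd.DataFrame(columns=["gene", "min_score", "n_stages_passed"])
    membrane = set(membrane_list)
    stages = list(required_stages) if required_stages else list(pd.unique(performance["stage"]))
    need = len(stages) if min_stages is None else min_stages
    rows = []
    for gene, sub in performance.groupby("gene"):
        if gene not in membrane:
            continue
        sub = sub[sub["stage"].isin(stages)]
        per_stage = sub.set_index("stage")[["sensitivity", "specificity"]].min(axis=1)
        passed = (sub.set_index("stage")["sensitivity"] > cutoff) & (
            sub.set_index("stage")["specificity"] > cutoff
        )
        if int(passed.sum()) >= need and len(sub) == len(stages):
            rows.append((gene, float(per_stage.min()), int(passed.sum())))
    out = pd.DataFrame(rows, columns=["gene", "min_score", "n_stages_passed"])
    return out.sort_values(["min_score", "gene"], ascending=[False, True]).reset_index(drop=True)


def read_gene_list(path: str) -> list[str]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
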