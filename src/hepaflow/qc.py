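"""Per-cell quality control: FPKM adjustment, spike-in diagnostics, outliers.

FPKM values produced against separate genome and spike-in references are
re-scaled by the share of sequencing reads each reference consumed.  Cell
outliers are flagged from in-matrix information only: a robust detected-gene
rule (median minus k scaled MADs) plus a floor on the median pairwise
spike-in correlation.  A second, sorted-population pass additionally removes
cells whose whole-transcriptome profile departs from the population median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

MIN_CELLS_FOR_OUTLIERS = 8


@dataclass
class QcReport:
    """Per-cell QC table plus run totals.

    ``per_cell`` is indexed by cell id with columns ``detected_genes``,
    ``spikein_corr`` (NaN when unavailable), ``outlier`` and, for the
    two-stage variant, ``stage2_removed`` and ``profile_corr``.
    """

    per_cell: pd.DataFrame
    cells_in: int
    cells_retained: int
    status: str = "ok"

    @property
    def retention_pct(self) -> float:
        """100 * retained / in, rounded half-up to one decimal."""
        return retention_percentage(self.cells_in, self.cells_retained)

    def retained_cells(self) -> pd.Index:
        flagged = self.per_cell["outlier"].astype(bool)
        if "stage2_removed" in self.per_cell:
            flagged = flagged | self.per_cell["stage2_removed"].astype(bool)
        return self.per_cell.index[~flagged]

    def summary_lines(self) -> list[str]:
        return [
            f"cells_in={self.cells_in}",
            f"cells_retained={self.cells_retained}",
            f"retention_pct={self.retention_pct}",
            f"status={self.status}",
        ]


def retention_percentage(cells_in: int, cells_retained: int) -> float:
    if cells_in <= 0:
        raise ValueError("cells_in must be positive")
    pct = Decimal(100 * cells_retained) / Decimal(cells_in)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def adjust_fpkm(matrix: ExpressionMatrix, stats_table: pd.DataFrame) -> ExpressionMatrix:
    """Re-scale FPKM by each cell's genome / spike-in read share.

    ``stats_table`` is indexed by cell id with integer columns
    ``genome_reads`` and ``spikein_reads``.  Gene rows are multiplied by
    the genomic read fraction, spike-in rows by the spike-in fraction;
    zeros are preserved exactly.
    """
    missing = matrix.cells.difference(stats_table.index)
    if len(missing):
        raise ValueError(f"read stats missing for cell {missing[0]!r}")
    g = stats_table.loc[matrix.cells, "genome_reads"].to_numpy(dtype=float)
    s = stats_table.loc[matrix.cells, "spikein_reads"].to_numpy(dtype=float)
    if np.any(g < 0) or np.any(s < 0):
        raise ValueError("read counts must be non-negative")
    total = g + s
    if np.any(total <= 0):
        bad = matrix.cells[np.argmax(total <= 0)]
        raise ValueError(f"cell {bad!r} has zero total reads")
    vals = matrix.values.to_numpy().copy()
    spike = matrix.spikein_mask
    vals[~spike, :] *= (g / total)[None, :]
    vals[spike, :] *= (s / total)[None, :]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=matrix.genes, columns=matrix.cells),
        matrix.spikein_mask.copy(),
    )


def spikein_correlation_qc(matrix: ExpressionMatrix) -> pd.Series:
    """Median pairwise Pearson correlation per cell on log2(FPKM+1) spike-ins.

    A cell with zero variance across spike-ins has undefined correlations
    and is reported as NaN, never as 0.
    """
    spk = matrix.spikeins()
    if spk.n_genes < 3:
        raise ValueError("need at least 3 spike-in rows")
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    logv = np.log2(spk.values.to_numpy() + 1.0)
    sd = logv.std(axis=0)
    valid = sd > 0
    n = logv.shape[1]
    corr = np.full((n, n), np.nan)
    if valid.sum() >= 2:
        sub = np.corrcoef(logv[:, valid], rowvar=False)
        corr[np.ix_(valid, valid)] = sub
    np.fill_diagonal(corr, np.nan)
    with np.errstate(all="ignore"):
        med = np.array(
            [np.nanmedian(corr[i]) if np.any(np.isfinite(corr[i])) else np.nan for i in range(n)]
        )
    return pd.Series(med, index=matrix.cells, name="spikein_corr")


def identify_outlier_cells(
    matrix: ExpressionMatrix,
    fpkm_threshold: float = 1.0,
    mad_k: float = 3.0,
    spikein_corr_min: float = 0.5,
) -> QcReport:
    """Flag low-quality cells on detected-gene count and spike-in agreement.

    A cell is an outlier iff detected-gene count < median - mad_k * scaled
    MAD, or (when >= 3 spike-in rows exist) its median spike-in correlation
    falls below ``spikein_corr_min``.
    """
    if matrix.n_cells < MIN_CELLS_FOR_OUTLIERS:
        raise ValueError(f"need at least {MIN_CELLS_FOR_OUTLIERS} cells for robust QC")
    detected = matrix.detected_gene_counts(fpkm_threshold)
    med = detected.median()
    mad = stats.median_abs_deviation(detected, scale="normal")
    low_genes = detected < med - mad_k * mad

    if matrix.spikein_mask.sum() >= 3:
        corr = spikein_correlation_qc(matrix)
        low_corr = corr.fillna(-np.inf) < spikein_corr_min
    else:
        corr = pd.Series(np.nan, index=matrix.cells, name="spikein_corr")
        low_corr = pd.Series(False, index=matrix.cells)

    outlier = low_genes | low_corr
    per_cell = pd.DataFrame(
        {
            "detected_genes": detected,
            "spikein_corr": corr,
            "outlier": outlier,
        }
    )
    return QcReport(
        per_cell=per_cell,
        cells_in=matrix.n_cells,
        cells_retained=int((~outlier).sum()),
    )


def two_stage_population_qc(
    matrix: ExpressionMatrix,
    profile_corr_min: float = 0.6,
    fpkm_threshold: float = 1.0,
    mad_k: float = 3.0,
    spikein_corr_min: float = 0.5,
) -> QcReport:
    """QC for a sorted population: outlier pass, then profile-similarity pass.

    Stage 1 applies :func:`identify_outlier_cells`; stage 2 removes
    survivors whose Pearson correlation (log2(FPKM+1), biological genes) to
    the median profile of the stage-1 survivors is below
    ``profile_corr_min``.
    """
    rep = identify_outlier_cells(matrix, fpkm_threshold, mad_k, spikein_corr_min)
    per_cell = rep.per_cell.copy()
    per_cell["stage2_removed"] = False
    per_cell["profile_corr"] = np.nan

    survivors = per_cell.index[~per_cell["outlier"]]
    if len(survivors) == 0:
        return QcReport(per_cell, rep.cells_in, 0, status="warning: all cells removed at stage 1")

    logv = np.log2(matrix.biological().values + 1.0)
    median_profile = logv[list(survivors)].median(axis=1).to_numpy()
    for cell in survivors:
        x = logv[cell].to_numpy()
        if x.std() == 0 or median_profile.std() == 0:
            r = np.nan
        else:
            r = np.corrcoef(x, median_profile)[0, 1]
        per_cell.loc[cell, "profile_corr"] = r
        if not np.isfinite(r) or r < profile_corr_min:
            per_cell.loc[cell, "stage2_removed"] = True

    retained = int((~(per_cell["outlier"] | per_cell["stage2_removed"])).sum())
    return QcReport(per_cell, rep.cells_in, retained)


def write_qc_report(report: QcReport, table_path: str, summary_path: str) -> None:
    report.per_cell.to_csv(table_path, sep="\t")
    with open(summary_path, "w") as fh:
        for line in report.summary_lines():
            fh.write(line + "\n")
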