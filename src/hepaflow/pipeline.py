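"""End-to-end orchestration: QC -> noise filter -> typing -> trajectory ->
TF network -> marker assessment, driven by one flat key=value config and a
single seed.  Also bundles a desk-scale demo dataset generator."""

from __future__ import annotations

import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import celltyping, markers, noise, qc, tfnet, trajectory
from .matrix import ExpressionMatrix, read_matrix, write_matrix
from .simulate import (
    CHOLANGIOCYTE_GENES,
    PANEL_GENES,
    SimConfig,
    simulate_cholangiocytes,
    simulate_fetal_liver,
)

DEMO_STAGES = ("E11.5", "E12.5", "E13.5", "E14.5", "E16.5")

ISOLATION_MARKERS = [
    "Dlk1", "Cdh1", "Anpep", "Prom1", "Gpc3", "Lgr5", "Cd24a",
    "Igdcc4", "Gcgr", "Cdhr2", "Afp",
]

MEMBRANE_DEMO = [
    "Cdh1", "Anpep", "Prom1", "Gcgr", "Cdhr2", "Lgr5", "Cd24a", "Igdcc4",
    "Epcam", "Kdr", "Lyve1", "Pdgfra", "Itga2b", "Itgb3",
]

TF_DEMO = [
    "Hnf4a", "Afp", "Alb", "Gpc3", "Dlk1", "Sox9", "Hes1", "Spp1",
    "Apoh", "Ahsg", "Mdk",
] + [f"TrajUp{i:02d}" for i in range(3, 16)] + [f"TrajDn{i:02d}" for i in range(2, 16)]


@dataclass
class PipelineConfig:
    """Flat run configuration; every stage parameter has its module default."""

    matrix: str = ""
    annotation: str = ""
    chol_matrix: str = ""
    chol_annotation: str = ""
    panels: str = ""
    tf_list: str = ""
    membrane_list: str = ""
    gmt: str = ""
    outdir: str = "hepaflow_out"
    seed: int = 0
    format: str = "tsv"
    fpkm_threshold: float = 1.0
    mad_k: float = 3.0
    spikein_corr_min: float = 0.5
    cv2_cut: float = 0.3
    max_frac: float = 0.05
    z: float = 1.96
    k_genes: int = 400
    min_cells: int = 3
    top_k: int = 30
    marker_cutoff: float = 0.5
    run_qc: bool = True
    run_noise: bool = True
    run_typing: bool = True
    run_trajectory: bool = True
    run_network: bool = True
    run_markers: bool = True

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        kwargs = {}
        fields = {f: t for f, t in cls.__annotations__.items()}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key, val = key.strip(), val.strip()
                if key not in fields:
                    raise KeyError(f"unknown config key: {key!r}")
                typ = fields[key]
                if typ == "bool":
                    kwargs[key] = val.lower() in ("1", "true", "yes")
                elif typ == "int":
                    kwargs[key] = int(val)
                elif typ == "float":
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for key in self.__annotations__:
                fh.write(f"{key}={getattr(self, key)}\n")


def make_demo(seed: int = 0, outdir: str = "demo") -> PipelineConfig:
    """Write a desk-scale synthetic dataset plus a ready-to-run config.

    Roughly 2000 genes + 92 spike-ins by ~400 cells over five stages, plus
    52 sorted Epcam-positive cells, with full ground truth.
    """
    os.makedirs(outdir, exist_ok=True)
    cfg = SimConfig(stages=DEMO_STAGES, cells_per_stage=80, outlier_fraction=0.1, seed=seed)
    matrix, annot, truth = simulate_fetal_liver(cfg)
    chol, chol_annot, chol_truth = simulate_cholangiocytes(
        cfg, 52, base=(matrix, annot, truth)
    )

    p = lambda name: os.path.join(outdir, name)
    write_matrix(matrix, p("matrix.tsv"), "tsv")
    write_matrix(matrix, p("matrix.mtx"), "mtx")
    annot.to_csv(p("annotation.tsv"), sep="\t")
    truth.to_tsv(p("truth_cells.tsv"), p("truth_genes.tsv"))
    write_matrix(chol, p("chol_matrix.tsv"), "tsv")
    chol_annot.to_csv(p("chol_annotation.tsv"), sep="\t")

    celltyping.MarkerPanelSet().to_config(p("panels.txt"))
    with open(p("tf_list.txt"), "w") as fh:
        fh.write("\n".join(TF_DEMO) + "\n")
    with open(p("membrane_list.txt"), "w") as fh:
        fh.write("\n".join(MEMBRANE_DEMO) + "\n")
    _write_demo_gmt(p("annotation.gmt"), matrix)

    run = PipelineConfig(
        matrix=p("matrix.tsv"),
        annotation=p("annotation.tsv"),
        chol_matrix=p("chol_matrix.tsv"),
        chol_annotation=p("chol_annotation.tsv"),
        panels=p("panels.txt"),
        tf_list=p("tf_list.txt"),
        membrane_list=p("membrane_list.txt"),
        gmt=p("annotation.gmt"),
        outdir=os.path.join(outdir, "out"),
        seed=seed,
    )
    run.to_file(p("config.txt"))
    return run


def _write_demo_gmt(path: str, matrix: ExpressionMatrix) -> None:
    hep = PANEL_GENES["hepatoblast"] + ["Apoh", "Ahsg", "Cdh1", "Anpep"]
    sets = {
        "liver_function": [g for g in hep if g in matrix.genes],
        "erythroid_oxygen_transport": PANEL_GENES["erythrocyte"] + ["Hba-a2", "Hbb-bs"],
        "immune_response": PANEL_GENES["macrophage"],
        "bile_duct_development": CHOLANGIOCYTE_GENES,
        "housekeeping_like": [f"Gene{i:05d}" for i in range(1, 40)],
    }
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write(term + "\tdemo\t" + "\t".join(genes) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; returns the machine-readable report.

    Outputs are written under ``config.outdir``; a failing stage is
    recorded in the report and earlier outputs are preserved.
    """
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}

    steps = [
        ("qc", config.run_qc, _stage_qc),
        ("noise", config.run_noise, _stage_noise),
        ("typing", config.run_typing, _stage_typing),
        ("trajectory", config.run_trajectory, _stage_trajectory),
        ("network", config.run_network, _stage_network),
        ("markers", config.run_markers, _stage_markers),
    ]
    for name, enabled, fn in steps:
        if not enabled:
            report["stages"][name] = {"status": "skipped"}
            continue
        t0 = time.time()
        try:
            info = fn(config, state)
            info["status"] = "ok"
        except Exception as exc:
            info = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            report["stages"][name] = info
            break
        info["seconds"] = round(time.time() - t0, 2)
        report["stages"][name] = info

    with open(os.path.join(config.outdir, "report.txt"), "w") as fh:
        fh.write(f"seed={config.seed}\n")
        for name, info in report["stages"].items():
            for key, val in info.items():
                fh.write(f"{name}.{key}={val}\n")
    return report


def _stage_qc(config: PipelineConfig, state: dict) -> dict:
    matrix = read_matrix(config.matrix, config.format)
    annot = pd.read_csv(config.annotation, sep="\t", index_col=0)
    rep = qc.identify_outlier_cells(
        matrix, config.fpkm_threshold, config.mad_k, config.spikein_corr_min
    )
    qc.write_qc_report(
        rep,
        os.path.join(config.outdir, "qc_cells.tsv"),
        os.path.join(config.outdir, "qc_summary.txt"),
    )
    state["matrix"] = matrix.subset_cells(list(rep.retained_cells()))
    state["annotation"] = annot.loc[list(rep.retained_cells())]
    out = {"cells_in": rep.cells_in, "cells_retained": rep.cells_retained,
           "retention_pct": rep.retention_pct}
    if config.chol_matrix:
        chol = read_matrix(config.chol_matrix, config.format)
        chol_rep = qc.two_stage_population_qc(
            chol, 0.6, config.fpkm_threshold, config.mad_k, config.spikein_corr_min
        )
        state["chol_matrix"] = chol.subset_cells(list(chol_rep.retained_cells()))
        out["chol_cells_in"] = chol_rep.cells_in
        out["chol_cells_retained"] = chol_rep.cells_retained
    return out


def _require(state: dict, key: str, producer: str) -> object:
    if key not in state:
        raise RuntimeError(f"stage requires {key!r}: enable the {producer} stage first")
    return state[key]


def _stage_noise(config: PipelineConfig, state: dict) -> dict:
    matrix: ExpressionMatrix = _require(state, "matrix", "qc")
    model = noise.TechnicalNoiseModel.from_matrix(
        matrix, cv2_cut=config.cv2_cut, max_frac=config.max_frac, z=config.z
    )
    results = model.fit()
    table = noise.filter_genes(model.moments, results)
    table.to_csv(os.path.join(config.outdir, "noise_filter.tsv"), sep="\t")
    with open(os.path.join(config.outdir, "noise_model.txt"), "w") as fh:
        fh.write(results.summary() + "\n")
    retained = list(table.index[table["retained"]])
    state["noise_model"] = results
    state["matrix_filtered"] = matrix.subset_genes(retained)
    return {"a0": round(results.a0, 6), "a1": round(results.a1, 6),
            "mu_th": round(results.mu_th, 6), "genes_retained": len(retained)}


def _stage_typing(config: PipelineConfig, state: dict) -> dict:
    matrix: ExpressionMatrix = _require(state, "matrix_filtered", "noise")
    annot: pd.DataFrame = _require(state, "annotation", "qc")
    panels = (
        celltyping.MarkerPanelSet.from_config(config.panels)
        if config.panels
        else celltyping.MarkerPanelSet()
    )
    clustering = celltyping.two_pass_decomposition(matrix, panels, k_genes=config.k_genes)
    types = clustering.cell_types()
    types.to_frame().to_csv(os.path.join(config.outdir, "cell_types.tsv"), sep="\t")
    if clustering.scores is not None:
        clustering.scores.to_csv(os.path.join(config.outdir, "cluster_scores.tsv"), sep="\t")
    props = celltyping.cell_type_proportions(types, annot["stage"])
    props.to_csv(os.path.join(config.outdir, "type_proportions.tsv"), sep="\t")
    display = celltyping.anova_rank_display_genes(matrix, types, k=config.k_genes)
    coords = celltyping.embed_tsne(matrix, display, seed=config.seed)
    coords.to_csv(os.path.join(config.outdir, "tsne.tsv"), sep="\t")
    if config.gmt:
        ann = celltyping.read_gmt(config.gmt)
        universe = set(matrix.biological().genes)
        hb_cells = types.index[types == "hepatoblast"]
        if len(hb_cells):
            hb_mean = matrix.log2p1()[list(hb_cells)].mean(axis=1)
            other_mean = matrix.log2p1()[[c for c in matrix.cells if c not in set(hb_cells)]].mean(axis=1)
            query = set((hb_mean - other_mean).nlargest(50).index) & universe
            enr = celltyping.go_overrepresentation(query, universe, ann)
            enr.to_csv(os.path.join(config.outdir, "go_enrichment.tsv"), sep="\t")
    state["cell_types"] = types
    return {"n_groups": int(types.nunique()), "cells": int(len(types))}


def _stage_trajectory(config: PipelineConfig, state: dict) -> dict:
    # the trajectory carries its own eligibility rule (detected in >= 3
    # cells), applied to the QC'd matrix rather than the noise-filtered
    # gene set, so stage-dynamic genes of moderate abundance stay visible
    matrix: ExpressionMatrix = _require(state, "matrix", "qc")
    annot: pd.DataFrame = _require(state, "annotation", "qc")
    types: pd.Series = _require(state, "cell_types", "typing")
    hb = types.index[types == "hepatoblast"]
    hb_matrix = matrix.subset_cells(list(hb))
    stage_order = list(dict.fromkeys(annot["stage"]))
    series = trajectory.stage_anova(
        hb_matrix, annot["stage"], stage_order,
        min_cells=config.min_cells, top_k=config.top_k,
        detection_threshold=config.fpkm_threshold,
    )
    out = series.anova.copy()
    out["trend"] = series.trends
    out.to_csv(os.path.join(config.outdir, "trajectory_genes.tsv"), sep="\t")
    _, coords = trajectory.build_track(hb_matrix, annot["stage"], series, seed=config.seed)
    coords.to_csv(os.path.join(config.outdir, "track_coords.tsv"), sep="\t")
    info = {"n_stages": len(series.stages), "top_k": len(series.top_genes)}
    if "chol_matrix" in state:
        table, summary = trajectory.nearest_stage_assignment(state["chol_matrix"], series)
        table.to_csv(os.path.join(config.outdir, "chol_stage_assignment.tsv"), sep="\t")
        info["chol_modal_stage"] = summary["modal_stage"]
    state["series"] = series
    state["hb_cells"] = list(hb)
    return info


def _stage_network(config: PipelineConfig, state: dict) -> dict:
    matrix: ExpressionMatrix = _require(state, "matrix", "qc")
    hb_cells: list = _require(state, "hb_cells", "trajectory")
    tfs = tfnet.read_tf_list(config.tf_list) if config.tf_list else TF_DEMO
    info: dict = {}
    if "chol_matrix" in state:
        chol: ExpressionMatrix = state["chol_matrix"]
        shared = [g for g in tfs if g in matrix.genes and g in chol.genes]
        joint = pd.concat(
            [matrix.values.loc[shared, hb_cells], chol.values.loc[shared]], axis=1
        )
        joint_m = ExpressionMatrix(joint)
        de = tfnet.screen_de_tfs(
            joint_m, hb_cells, list(chol.cells), shared, alpha=0.01
        )
        de.to_csv(os.path.join(config.outdir, "de_tfs.tsv"), sep="\t")
        selected = list(de.index[de["significant"]])
        info["n_de_tfs"] = len(selected)
    else:
        selected = [g for g in tfs if g in matrix.genes]
    if len(selected) >= 2:
        corr = tfnet.tf_correlation_matrix(matrix, selected, hb_cells)
        net = tfnet.build_covariance_network(corr)
        tfnet.export_network(net, os.path.join(config.outdir, "tf_network.tsv"),
                             layout_seed=config.seed)
        info["n_nodes"] = net.number_of_nodes()
        info["n_edges"] = net.number_of_edges()
        info["hubs"] = ",".join(t for t, _ in tfnet.hub_ranking(net)[:5])
    else:
        info["n_nodes"] = 0
        info["n_edges"] = 0
    return info


def _stage_markers(config: PipelineConfig, state: dict) -> dict:
    matrix: ExpressionMatrix = _require(state, "matrix", "qc")
    annot: pd.DataFrame = _require(state, "annotation", "qc")
    types: pd.Series = _require(state, "cell_types", "typing")
    genes = [g for g in ISOLATION_MARKERS if g in matrix.genes]
    perf = markers.assess_markers(
        matrix, types, annot["stage"], genes, "hepatoblast",
        threshold=config.fpkm_threshold,
    )
    perf.to_csv(os.path.join(config.outdir, "marker_performance.tsv"), sep="\t", index=False)
    membrane = (
        markers.read_gene_list(config.membrane_list) if config.membrane_list else MEMBRANE_DEMO
    )
    all_perf = markers.assess_markers(
        matrix, types, annot["stage"],
        [g for g in membrane if g in matrix.genes], "hepatoblast",
        threshold=config.fpkm_threshold,
    )
    pred = markers.predict_markers(all_perf, membrane, cutoff=config.marker_cutoff)
    pred.to_csv(os.path.join(config.outdir, "marker_predictions.tsv"), sep="\t", index=False)
    best = perf.assign(minscore=perf[["sensitivity", "specificity"]].min(axis=1))
    best_gene = (
        best.groupby("gene")["minscore"].mean().sort_values(ascending=False).index[0]
        if len(best)
        else ""
    )
    return {"n_assessed": len(genes), "n_predicted": len(pred), "best_marker": best_gene}
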