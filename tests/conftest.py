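import numpy as np
import pandas as pd
import pytest

from hepaflow.matrix import ExpressionMatrix
from hepaflow.simulate import SimConfig, simulate_cholangiocytes, simulate_fetal_liver

FIVE_STAGES = ("E11.5", "E12.5", "E13.5", "E14.5", "E16.5")


@pytest.fixture(scope="session")
def default_sim():
    """Default six-type simulation: 2000 genes + 92 spike-ins, 400 cells."""
    cfg = SimConfig(stages=FIVE_STAGES, cells_per_stage=80, seed=1)
    matrix, annotation, truth = simulate_fetal_liver(cfg)
    return cfg, matrix, annotation, truth


@pytest.fixture(scope="session")
def chol_sim(default_sim):
    cfg, matrix, annotation, truth = default_sim
    return simulate_cholangiocytes(cfg, 52, base=(matrix, annotation, truth))


@pytest.fixture(scope="session")
def single_type_sim():
    """One stage, hepatoblasts only: the technical-noise recovery setting."""
    props = {"E11.5": {
        "hepatoblast": 1.0, "mesenchymal": 0.0, "endothelial": 0.0,
        "erythrocyte": 0.0, "macrophage": 0.0, "megakaryocyte": 0.0,
    }}
    cfg = SimConfig(
        n_genes=2200, stages=("E11.5",), cells_per_stage=200,
        type_proportions=props, noise_a0=0.05, noise_a1=4.0, seed=7,
    )
    return cfg, *simulate_fetal_liver(cfg)


def toy_matrix(values, genes=None, cells=None, spikein_mask=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cells), spikein_mask
    )
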