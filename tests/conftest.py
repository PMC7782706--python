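import numpy as np
import pandas as pd
import pytest

from pvseq.data import CellTable, Dataset, ExpressionMatrix
from pvseq.simulate import DESpec, SimulationConfig, simulate_expression


def make_dataset(tpm: np.ndarray, ages=None, types=None) -> Dataset:
    """Build a small aligned Dataset from a raw gene x cell array."""
    n_genes, n_cells = tpm.shape
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{i}" for i in range(n_cells)]
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=cells))
    meta = CellTable(pd.DataFrame({
        "cell_id": cells,
        "age_days": ages if ages is not None else [20] * n_cells,
        "morph_type": types if types is not None else ["vBC"] * n_cells,
    }))
    return Dataset(expr, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def two_type_dataset():
    """100+100 cells, 300 genes, one planted 8-fold gene between the types."""
    cfg = SimulationConfig(
        n_cells_per_type={"vBC": 100, "SST-OLM": 100},
        n_genes=300,
        dropout_rate=0.2,
        de_spec=[DESpec(gene_index=7, type_a="vBC", type_b="SST-OLM", fold=8.0)],
        seed=11,
    )
    ds, truth = simulate_expression(cfg)
    return ds, truth
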