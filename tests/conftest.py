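import numpy as np
import pandas as pd
import pytest

from syncytx.expression import ExpressionMatrix
from syncytx.simulate import SimulationConfig


@pytest.fixture
def small_cfg():
    """Cheap config for fast unit tests."""
    return SimulationConfig(
        domain_size=(200.0, 200.0),
        n_grids=(6, 6),
        n_genes=300,
        n_markers_per_program=15,
        libsize_grid=50_000.0,
        n_nuclei=200,
        n_amoebae=100,
        seed=0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, layer="counts", gene_ids=None, sample_ids=None, meta=None):
    values = np.asarray(values)
    g, s = values.shape
    gene_ids = gene_ids if gene_ids is not None else [f"g{i}" for i in range(g)]
    sample_ids = sample_ids if sample_ids is not None else [f"s{j}" for j in range(s)]
    if meta is not None:
        meta = pd.DataFrame(meta, index=sample_ids)
    return ExpressionMatrix(
        values=values,
        layer=layer,
        gene_ids=np.asarray(gene_ids, dtype=object),
        sample_ids=np.asarray(sample_ids, dtype=object),
        sample_meta=meta,
    )
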