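import numpy as np
import pandas as pd
import pytest

import htrmap as hm


@pytest.fixture(scope="session")
def small_config():
    return hm.default_config(seed=11, n_cells_scrna=2_000, n_cells_spatial=2_000)


@pytest.fixture(scope="session")
def small_cells(small_config):
    return hm.generate_taxonomy(small_config)


@pytest.fixture(scope="session")
def small_expr(small_config, small_cells):
    return hm.generate_expression(small_cells, small_config)


@pytest.fixture(scope="session")
def small_mask(small_expr):
    return hm.detect(small_expr)


@pytest.fixture(scope="session")
def small_spatial(small_config):
    return hm.generate_spatial(small_config)


def random_fixture(seed: int, n_cells: int = 300, n_genes: int = 14):
    """A random joined fixture: cells with taxonomy labels, expression, mask."""
    rng = np.random.default_rng(seed)
    genes = [f"g{j:02d}" for j in range(n_genes)]
    n_clusters = int(rng.integers(3, 9))
    cluster = rng.integers(0, n_clusters, size=n_cells)
    cells = pd.DataFrame(
        {
            "cell_label": [f"c{i:05d}" for i in range(n_cells)],
            "cluster": [f"k{c}" for c in cluster],
            "supertype": [f"st{c // 2}" for c in cluster],
            "subclass": [f"sc{c // 2}" for c in cluster],
            "class": [f"cl{c % 3}" for c in cluster],
            "neighborhood": [f"nb{c % 2}" for c in cluster],
            "neurotransmitter": [f"nt{c % 4}" for c in cluster],
        }
    )
    values = np.where(rng.random((n_cells, n_genes)) < 0.35,
                      rng.uniform(0.0, 8.0, size=(n_cells, n_genes)), 0.0)
    expr = pd.DataFrame(values, index=pd.Index(cells["cell_label"], name="cell_label"),
                        columns=genes)
    return cells, expr
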