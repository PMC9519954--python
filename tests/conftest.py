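import numpy as np
import pandas as pd
import pytest

import gliastate as gs


@pytest.fixture
def small_design():
    """Two-condition design with a +2 panel and a balancing -2 panel."""
    return gs.SyntheticDesign(
        n_genes=2000,
        conditions=[("ctl", 4), ("hi", 4)],
        panels=[
            gs.PanelSpec("up", np.arange(100), {"hi": 2.0}),
            gs.PanelSpec("down", np.arange(100, 200), {"hi": -2.0}),
        ],
        baseline_range=(5.0, 9.0),
        dispersion=0.05,
        library_sizes=1e6,
        seed=11,
    )


@pytest.fixture
def toy_deg_table():
    return pd.DataFrame(
        {
            "logFC": [2.5, 2.0, 1.9, -3.0, 0.0],
            "logCPM": [5.0, 6.0, 7.0, 4.0, 3.0],
            "PValue": [1e-6, 1e-4, 0.2, 1e-8, 0.9],
            "FDR": [5e-6, 2.5e-4, 0.25, 1e-7, 0.9],
        },
        index=pd.Index(["ga", "gb", "gc", "gd", "ge"], name="gene"),
    )


def make_vector(values, genes=None, **kw):
    genes = genes or [f"g{i}" for i in range(len(values))]
    return gs.StateChangeVector(values=pd.Series(values, index=genes, dtype=float), **kw)
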