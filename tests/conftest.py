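import numpy as np
import pandas as pd
import pytest

import biogaps as bg


@pytest.fixture(scope="session")
def default_landscape():
    """400-cell landscape with a rho=0.75 proxy, the standard study setting."""
    land = bg.make_landscape(400, 20, seed=11)
    return bg.attach_proxy(land, 0.75, seed=12)


@pytest.fixture(scope="session")
def dense_counts(default_landscape):
    return bg.simulate_counts(default_landscape, alpha=1.0, beta=0.8, seed=13)


@pytest.fixture()
def small_observed():
    """Hand-sized observed dataset for closed-form estimator checks."""
    table = pd.DataFrame(
        {
            "cell_id": np.arange(4),
            "x_proxy_level": [1, 1, 2, 2],
            "count": [2, 4, 6, 8],
        }
    )
    return bg.AbundanceData(table=table, unit_cols=("cell_id",), meta={})
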