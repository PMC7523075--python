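import numpy as np
import pandas as pd
import pytest

import plantcompart as pc


@pytest.fixture
def toy_table():
    """5 OTUs x 4 samples with hand-countable totals; valid design names."""
    counts = pd.DataFrame(
        {
            "C1aS": [30, 5, 9, 0, 2],
            "C1aR": [40, 3, 1, 0, 0],
            "C1aN": [50, 0, 0, 1, 0],
            "C1aL": [20, 6, 0, 2, 0],
        },
        index=[f"Otu{i}" for i in range(1, 6)],
    )
    return pc.OtuTable(counts)


@pytest.fixture(scope="session")
def sim_table():
    """Small full-design synthetic experiment shared across tests."""
    cfg = pc.SimulationConfig(n_otus=80, n_replicates=3, seed=11)
    return pc.generate_experiment(cfg)


@pytest.fixture(scope="session")
def sim_dissimilarity(sim_table):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pc.iterative_bray_curtis(
            sim_table, depth=800, iterations=10, seed=3
        )
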