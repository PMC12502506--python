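import logging

import numpy as np
import pandas as pd
import pytest

from ripnet.core_io import AbundanceTable, EnvTable

logging.getLogger("ripnet").setLevel(logging.ERROR)


@pytest.fixture
def small_table() -> AbundanceTable:
    """3 taxa x 4 samples, two groups of two."""
    counts = pd.DataFrame(
        [[10, 0, 3, 7], [5, 5, 5, 5], [0, 20, 2, 8]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["a1", "a2", "b1", "b2"],
    )
    taxonomy = pd.Series(
        ["Proteobacteria", "Ascomycota", "Unclassified"], index=counts.index
    )
    groups = pd.Series(["A", "A", "B", "B"], index=counts.columns)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, groups=groups)


@pytest.fixture
def eight_sample_table() -> AbundanceTable:
    """8-sample table with monotone, anti-monotone and noisy taxa."""
    rng = np.random.default_rng(42)
    n = 8
    up = np.arange(1, n + 1)
    counts = pd.DataFrame(
        {
            f"s{i + 1}": [up[i], 2 * up[i], n + 1 - up[i], rng.integers(1, 50)]
            for i in range(n)
        },
        index=["mono_a", "mono_b", "anti", "noise"],
    )
    taxonomy = pd.Series("Unclassified", index=counts.index)
    groups = pd.Series("G", index=counts.columns)
    return AbundanceTable(counts=counts, taxonomy=taxonomy, groups=groups)


@pytest.fixture
def env_table() -> EnvTable:
    data = pd.DataFrame(
        {
            "SOM": [1.0, 2.0, 3.0, 4.0],
            "BD": [1.5, 1.4, 1.3, 1.2],
            "constant": [7.0, 7.0, 7.0, 7.0],
        },
        index=["a1", "a2", "b1", "b2"],
    )
    return EnvTable(data)
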