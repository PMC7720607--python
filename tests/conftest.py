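import numpy as np
import pandas as pd
import pytest

import regendiv as rd


@pytest.fixture(scope="session")
def small_dataset():
    """A 2,000-gene simulated dataset shared by read-only tests."""
    cfg = rd.SimulationConfig(n_genes=2000, seed=101)
    cm, truth = rd.simulate_counts(cfg)
    return cfg, cm, truth


@pytest.fixture(scope="session")
def small_de_tables(small_dataset):
    """AO-vs-NM exact-test tables at the three timepoints (nb mode)."""
    _, cm, _ = small_dataset
    phi = rd.estimate_common_dispersion(
        cm, [cm.samples_of(c) for c in rd.ALL_CONDITIONS]
    )
    tables = {}
    for tp in ("12hpt", "24hpt", "untreated"):
        tables[tp] = rd.exact_test(
            cm, cm.samples_of(f"AO_{tp}"), cm.samples_of(f"NM_{tp}"),
            dispersion=phi, contrast=f"AO_{tp} vs NM_{tp}",
        )
    return tables


@pytest.fixture()
def toy_counts():
    """8-gene, 2-sample integer matrix with unequal libraries."""
    rng = np.random.default_rng(5)
    counts = pd.DataFrame(
        {
            "s1": [120, 30, 55, 400, 12, 75, 230, 8],
            "s2": [90, 70, 40, 820, 25, 60, 180, 30],
        },
        index=[f"g{i}" for i in range(8)],
    )
    assert (counts >= 0).all().all()
    return counts
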