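import itertools

import numpy as np
import pandas as pd
import pytest

from edanet import SimulationConfig, generate_dataset
from edanet.io import CountMatrix, SampleTable


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 400-gene dataset with planted effects for unit tests."""
    cfg = SimulationConfig(
        n_genes=400,
        n_modules=3,
        module_size=40,
        n_deg=40,
        n_dsg=20,
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def sample_table_36():
    rows = []
    for fam, gt, sex in itertools.product("ABC", ["CC", "CL", "LL"], "FM"):
        for rep in (1, 2):
            rows.append((f"{fam}_{gt}_{sex}{rep}", gt, fam, sex))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "family", "sex"]
    ).set_index("sample_id")
    return SampleTable(frame)


@pytest.fixture
def toy_counts():
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 200, size=(20, 3))
    return CountMatrix([f"g{i}" for i in range(20)], ["s1", "s2", "s3"], counts)
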