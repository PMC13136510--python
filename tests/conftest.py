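import logging

import numpy as np
import pandas as pd
import pytest

from adaptscape.datatypes import EnvTable, GenotypeMatrix, VarMeta

logging.getLogger("adaptscape").setLevel(logging.ERROR)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """3 individuals x 5 loci with one missing call, two sites."""
    dosages = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 0, 2, np.nan],
            [2, 0, 1, 2, 0],
        ],
        dtype=float,
    )
    ids = ["i1", "i2", "i3"]
    return GenotypeMatrix(
        dosages,
        locus_ids=[f"chr1:{100 + j}" for j in range(5)],
        individual_ids=ids,
        site_of={"i1": "sA", "i2": "sA", "i3": "sB"},
    )


def env_from_frame(df: pd.DataFrame, binary: tuple[str, ...] = ()) -> EnvTable:
    meta = {
        c: VarMeta(category="hydroclimatic", type="binary" if c in binary else "continuous")
        for c in df.columns
    }
    return EnvTable(values=df, var_meta=meta)


@pytest.fixture
def tiny_env() -> EnvTable:
    df = pd.DataFrame(
        {"temp": [1.0, 2.0, 3.0], "flow": [10.0, 30.0, 20.0]},
        index=["sA", "sB", "sC"],
    )
    df.index.name = "site_id"
    return env_from_frame(df)


@pytest.fixture(scope="session")
def demo_bundle():
    """The default demo scenario, shared across tests that only read it."""
    from adaptscape.simulate import default_config, make_scenario

    return make_scenario(default_config(seed=11))
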