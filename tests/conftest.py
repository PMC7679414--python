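import numpy as np
import pandas as pd
import pytest

from secretomenet.io import AbundanceTable, EnzymeClassMap
from secretomenet.simulate import SyntheticConfig, generate_study


@pytest.fixture(scope="session")
def class_map():
    return EnzymeClassMap.default()


@pytest.fixture(scope="session")
def small_config():
    """A two-fungus study small enough for per-test use."""
    return SyntheticConfig(
        n_fungi=2,
        n_proteins=40,
        class_catalog=[
            ("endoglucanase", 5),
            ("cellobiohydrolase", 5),
            ("xylanase", 5),
            ("laccase", 5),
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config, class_map):
    return generate_study(small_config, class_map)


@pytest.fixture(scope="session")
def default_study(class_map):
    return generate_study(SyntheticConfig(seed=7), class_map)


def make_table(values, protein_ids, sample_keys, scale="linear"):
    """Small helper: build an AbundanceTable from explicit sample triples."""
    columns = pd.MultiIndex.from_tuples(
        sample_keys, names=["fungus", "substrate", "replicate"]
    )
    df = pd.DataFrame(np.asarray(values, dtype=float), index=protein_ids, columns=columns)
    return AbundanceTable(df, scale=scale)
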