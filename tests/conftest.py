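import numpy as np
import pandas as pd
import pytest

from seedshift.association import GenotypeTable
from seedshift.energy_params import default_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240617)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def table1_counts():
    """The published genotype counts bundled with the package."""
    from importlib import resources
    with resources.files("seedshift.data").joinpath("table1_counts.csv").open() as fh:
        return pd.read_csv(fh)


@pytest.fixture
def rs4937333_table():
    return GenotypeTable("rs4937333", ("CC", "CT", "TT"), (21, 24, 21), (15, 24, 3))


def random_seq(rng, n, alphabet="ACGU"):
    return "".join(rng.choice(list(alphabet), size=n))
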