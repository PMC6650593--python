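import numpy as np
import pandas as pd
import pytest

from mran.datamodel import (
    CYANOBACTERIAL,
    ENVIRONMENTAL,
    NON_CYANOBACTERIAL,
    AbundanceTable,
)


def make_table(values, features, classes, sites=None, depths=None, dates=None):
    """Build an AbundanceTable from a plain array for unit tests."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    sites = sites if sites is not None else ["S1"] * n
    depths = depths if depths is not None else [0.0] * n
    if dates is None:
        dates = [str(p) for p in pd.period_range("2016-06", periods=n, freq="M")]
    idx = pd.MultiIndex.from_tuples(
        list(zip(sites, depths, dates)), names=("site", "depth", "date")
    )
    data = pd.DataFrame(values, index=idx, columns=features)
    return AbundanceTable(data, pd.Series(dict(zip(features, classes)), dtype=object))


@pytest.fixture
def simple_table():
    """3 OTUs (one cyanobacterial) + 1 environmental variable over 5 months."""
    rng = np.random.default_rng(0)
    otus = rng.dirichlet([5.0, 3.0, 2.0], size=5)
    chl = np.array([2.0, 5.0, 20.0, 18.0, 3.0])
    values = np.column_stack([otus, chl])
    return make_table(
        values,
        ["OTU1", "OTU2", "OTU3", "chl_a"],
        [CYANOBACTERIAL, NON_CYANOBACTERIAL, NON_CYANOBACTERIAL, ENVIRONMENTAL],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """A small default-ish generated dataset reused across read-only tests."""
    from mran.simulate import GeneratorConfig, generate_dataset

    cfg = GeneratorConfig(n_otus=30, n_modules=3, n_cyano_otus=3, seed=123)
    return generate_dataset(cfg)
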