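import numpy as np
import pandas as pd
import pytest

from wolfdemes import SampleSet, build_default_graph
from wolfdemes.demes import DemeGraph


@pytest.fixture(scope="session")
def graph():
    return build_default_graph()


@pytest.fixture(scope="session")
def two_deme_graph():
    return DemeGraph(
        demes=("A", "B"),
        edges=(("A", "B"),),
        stat_groups={"A": "EUR", "B": "ME"},
    )


@pytest.fixture(scope="session")
def line3_graph():
    """Three demes in a line, one stat group per deme."""
    return DemeGraph(
        demes=("A", "B", "C"),
        edges=(("A", "B"), ("B", "C")),
        stat_groups={"A": "EUR", "B": "ME", "C": "EAS"},
    )


def make_samples(spec):
    """SampleSet from [(id, deme, age), ...] or [(id, deme, age, lat, lon), ...]."""
    cols = ["id", "deme", "age_ky"] + (["lat", "lon"] if len(spec[0]) == 5 else [])
    return SampleSet(pd.DataFrame(spec, columns=cols))


@pytest.fixture
def pair_samples():
    """Two modern samples in one deme of the default graph."""
    return make_samples([("a", "Europe", 0.0), ("b", "Europe", 0.0)])


def three_sigma(values, expected=None):
    v = np.asarray(values, dtype=float)
    return 3.0 * v.std(ddof=1) / np.sqrt(len(v))
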