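import numpy as np
import pandas as pd
import pytest

from hotscan import SynthConfig, simulate_dataset
from hotscan.classify import classify_sites
from hotscan.intervals import IntervalSet


@pytest.fixture(scope="session")
def default_truth():
    """One default-scale synthetic dataset shared across read-only tests."""
    return simulate_dataset(SynthConfig(seed=3))


@pytest.fixture(scope="session")
def default_classified(default_truth):
    t = default_truth
    return classify_sites(t.sites, t.peaks["h3k4me3_a"], t.peaks["h3k4me3_b"],
                          t.peaks["dmc1"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_set(label, rows, extra_cols=()):
    cols = ["chrom", "start", "end", *extra_cols]
    return IntervalSet(label, pd.DataFrame(rows, columns=cols))


@pytest.fixture()
def interval_factory():
    return make_set
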