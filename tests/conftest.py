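import numpy as np
import pandas as pd
import pytest

import metabokit as mk


@pytest.fixture
def small_table():
    """4 samples x 3 features, two groups of 2 (integrity intentionally
    marginal; used for I/O round trips, not statistics)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0],
         [2.0, 4.0, 6.0],
         [10.0, 8.0, 6.0],
         [12.0, 9.0, 5.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["f1", "f2", "f3"])
    group = pd.Series(["A", "A", "B", "B"], index=values.index, name="Label")
    return mk.DataTable(values=values, group=group)


@pytest.fixture
def clean_table():
    """Two clean groups of 5 samples, 4 features."""
    rng = np.random.default_rng(11)
    values = pd.DataFrame(np.exp(rng.normal(2, 0.5, size=(10, 4))),
                          index=[f"s{i}" for i in range(10)],
                          columns=[f"f{j}" for j in range(4)])
    group = pd.Series(["A"] * 5 + ["B"] * 5, index=values.index, name="Label")
    return mk.DataTable(values=values, group=group)


@pytest.fixture
def signal_table():
    """20/group, 100 features, 5 informative at 2-SD log-scale separation,
    normalized (log10 + auto scale)."""
    dt = mk.make_two_group(mk.FixtureSpec(
        n_per_group=20, n_features=100, n_informative=5, effect_size=2.0,
        seed=42))
    return mk.normalize(dt, mk.NormalizationSpec("none", "log10", "auto"))


@pytest.fixture
def null_table():
    """40 samples, 100 features, labels independent of the data."""
    dt = mk.make_two_group(mk.FixtureSpec(
        n_per_group=20, n_features=100, n_informative=0, effect_size=0.0,
        seed=43))
    return mk.normalize(dt, mk.NormalizationSpec("none", "log10", "auto"))


@pytest.fixture(scope="session")
def compound_library():
    return mk.load_library()


@pytest.fixture(scope="session")
def pathway_library():
    return mk.make_pathway_library(n_pathways=8, size_range=(5, 12),
                                   planted="planted_pathway", seed=17)
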