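import pytest

import riskevo as rv


@pytest.fixture(scope="session")
def bird_table_path():
    return rv.bundled_risk_table_path()


@pytest.fixture(scope="session")
def balanced4():
    """Balanced 4-tip ultrametric tree: two cherries splitting at t=0.5."""
    return rv.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def fixture_dataset():
    """Synthetic 48-species dataset with the real category composition."""
    table, tree = rv.make_fixture_dataset(seed=12345)
    states = rv.CodedStates(states={
        row.species: {"EN": 1, "VU": 2, "NT": 3, "LC": 4}[row.iucn]
        for row in table.itertuples()
    })
    return table, tree, states
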