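import pytest

from ordbench import GenConfig, SchemaSpec, gen_corpus


@pytest.fixture(scope="session")
def spec():
    return SchemaSpec.default()


@pytest.fixture(scope="session")
def small_corpus():
    return gen_corpus(GenConfig(n_reactions=12, seed=42))


@pytest.fixture()
def compound_pair():
    """Two compounds differing in the amount value, one carrying an extra
    reaction_role leaf — the canonical single-message alteration case."""
    gt = {
        "identifiers": [{"type": "NAME", "value": "sodium hydride"}],
        "amount": {"mass": {"value": 5.0, "units": "GRAM"}},
    }
    pred = {
        "identifiers": [{"type": "NAME", "value": "sodium hydride"}],
        "amount": {"mass": {"value": 7.0, "units": "GRAM"}},
        "reaction_role": "REACTANT",
    }
    return gt, pred
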