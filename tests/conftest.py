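import pytest

from consortia_logic import default_params, generate_fixtures, named


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def fixture_pairs():
    """Seeded (truth table, realizing circuit) pairs over 2 and 3 inputs."""
    return generate_fixtures(seed=20130228, n=3, count=25) + \
        generate_fixtures(seed=20130228, n=2, count=10)


@pytest.fixture
def xor2():
    return named("XOR2")


@pytest.fixture
def fig2a_design():
    """The published XOR decomposition: (A OR B) AND NOT(A AND B)."""
    from consortia_logic import CircuitDesign
    return CircuitDesign.from_json({
        "inputs": ["Ara", "Sal"],
        "gates": [
            {"id": "and_in", "kind": "AND", "src": ["Ara", "Sal"]},
            {"id": "not_w", "kind": "NOT", "src": ["and_in"]},
            {"id": "or_in", "kind": "OR", "src": ["Ara", "Sal"]},
            {"id": "and_out", "kind": "AND", "src": ["or_in", "not_w"]},
        ],
        "output": "and_out",
    })
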