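import pytest

from isletquant import GateThresholds, SimulationConfig, gate_cells, generate_section


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic section (16 mm², 50 islets), shared read-only."""
    return generate_section(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def gated_default(default_dataset):
    return gate_cells(default_dataset.cells, GateThresholds.default())
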