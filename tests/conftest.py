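import pytest

from lakecarbon.pipeline import run_lake_pipeline
from lakecarbon.synthetic import LakeScenario, generate_lake


@pytest.fixture(scope="session")
def noiseless_lake():
    """Noise-free synthetic lake: (scenario, dataset, truth)."""
    scenario = LakeScenario(seed=1).noiseless()
    dataset, truth = generate_lake(scenario)
    return scenario, dataset, truth


@pytest.fixture(scope="session")
def noiseless_result(noiseless_lake):
    _, dataset, _ = noiseless_lake
    return run_lake_pipeline(dataset)


@pytest.fixture(scope="session")
def noisy_lake():
    """Synthetic lake with default field-scale noise: (scenario, dataset, truth)."""
    scenario = LakeScenario(seed=7)
    dataset, truth = generate_lake(scenario)
    return scenario, dataset, truth
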