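import pytest

from pachyscan.pipeline import PipelineResult, run_pipeline
from pachyscan.synthetic import SimulatedDataset, SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def result(config) -> PipelineResult:
    """Full pipeline run on the default synthetic dataset (seed 1)."""
    return run_pipeline(config)


@pytest.fixture(scope="session")
def dataset(result) -> SimulatedDataset:
    return result.dataset
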