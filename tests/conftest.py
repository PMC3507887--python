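import pytest

from twotissue.pipeline import PipelineConfig
from twotissue.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """A fast, fully default-structured study at reduced probe count."""
    return SimConfig(n_probes=3000, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()
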