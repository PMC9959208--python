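import pytest

from venomest.report import PipelineConfig, run_pipeline
from venomest.synthetic import GeneratorConfig, generate_library


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A small zero-noise library: 35 genes, ~120 ESTs."""
    return GeneratorConfig(
        n_toxin_genes=12,
        n_cellular_genes=15,
        n_random_genes=8,
        n_toxin_ests=60,
        n_cellular_ests=40,
        n_random_ests=20,
        sub_rate=0.0,
        trunc_prob=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_library(small_config):
    return generate_library(small_config)


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(PipelineConfig(generator=small_config))
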