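import numpy as np
import pytest

from borealcarbon.config import GeneratorConfig, PipelineConfig


@pytest.fixture
def small_generator():
    """A catchment small enough for fast end-to-end runs."""
    return GeneratorConfig(
        n_plots=36, grid_spacing=60.0, wetness_cell_size=2.0, correlation_length=20.0, seed=4
    )


@pytest.fixture
def small_pipeline_config(small_generator):
    return PipelineConfig(generator=small_generator, seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
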