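import numpy as np
import pytest

from otoage.pipeline import DatasetTable
from otoage.synthetic import (PopulationConfig, RenderParams,
                              sample_population, tiny_study_config)


@pytest.fixture(scope="session")
def small_population():
    """80 records at 32 px: enough structure for pipeline/CV tests, fast."""
    return sample_population(tiny_study_config(n_total=80, seed=3,
                                               canvas_size=32))


@pytest.fixture(scope="session")
def small_table(small_population):
    return DatasetTable.from_records(small_population)


@pytest.fixture(scope="session")
def render_params_128():
    """Render geometry at 128 px, where boundary measurements are reliable."""
    return RenderParams(canvas_size=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def metadata_population():
    """A large population sampled without images, for distributional checks."""
    cfg = PopulationConfig(n_total=10_000, seed=7)
    return sample_population(cfg, with_images=False)
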