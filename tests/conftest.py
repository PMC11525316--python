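import numpy as np
import pytest

from artbox import ReproductionGenSpec, SimilarityGenSpec, ToneSpaceConfig
from artbox.simulate import gen_reproduction_study, gen_similarity_study


@pytest.fixture(scope="session")
def config():
    return ToneSpaceConfig()


@pytest.fixture(scope="session")
def small_similarity_study():
    """Compact two-set rating study: 3 participants per set, low noise."""
    spec = SimilarityGenSpec(n_participants_per_set=3, noise_sd=0.3, seed=11)
    return spec, gen_similarity_study(spec)


@pytest.fixture(scope="session")
def small_reproduction_study():
    """Compact reproduction study: 4 participants, default design."""
    spec = ReproductionGenSpec(n_participants=4, seed=13)
    return spec, gen_reproduction_study(spec)


@pytest.fixture
def regular_polygon():
    def make(n, radius=1.0, phase=0.0):
        theta = 2.0 * np.pi * np.arange(n) / n + phase
        return radius * np.column_stack([np.cos(theta), np.sin(theta)])

    return make
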