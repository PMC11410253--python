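import numpy as np
import pytest
from hypothesis import settings

from ortholens.experiments import ScaledProfile, run_scaled_experiment
from ortholens.stimgen import DEFAULT_CANVAS

settings.register_profile("deterministic", derandomize=True,
                          database=None)
settings.load_profile("deterministic")

EMERGENCE_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def scaled_canvas():
    return DEFAULT_CANVAS.scaled(64)


@pytest.fixture(scope="session")
def emergence_results():
    """Literate/illiterate training + probing for three seeds.

    This is the expensive shared fixture behind the scaled literacy
    checks (word accuracy, selectivity contrast, dissimilarity,
    ordinal-unit emergence); it runs the experiment once per seed.
    """
    return [run_scaled_experiment(seed=s, profile=ScaledProfile())
            for s in EMERGENCE_SEEDS]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
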