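import numpy as np
import pytest

from ankleflex.estimation import fit_gains
from ankleflex.simulate import AnkleModel
from ankleflex.synthetic import GeneratorConfig, make_identification_dataset

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:
    pass


@pytest.fixture(scope="session")
def model():
    return AnkleModel.default()


@pytest.fixture(scope="session")
def gen_cfg():
    """The identification study conditions (noise-free, fixed seed)."""
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def identification_dataset(gen_cfg):
    return make_identification_dataset(gen_cfg)


@pytest.fixture(scope="session")
def com_fit(identification_dataset, gen_cfg):
    """Standard identification of the COM-feedback model."""
    return fit_gains(identification_dataset, model=gen_cfg.model, n_starts=5, seed=0)


@pytest.fixture(scope="session")
def default_fit(identification_dataset, gen_cfg):
    """Identification of the reduced (no-COM-feedback) model on the same data."""
    return fit_gains(
        identification_dataset,
        model=gen_cfg.model,
        n_starts=5,
        seed=0,
        use_com_feedback=False,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
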