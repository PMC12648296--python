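import numpy as np
import pytest

from excitonscope.synthetic import GeneratorConfig, make_complex


@pytest.fixture(scope="session")
def gen_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=11, n_frames=500)


@pytest.fixture(scope="session")
def assembly(gen_cfg):
    return make_complex(gen_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
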