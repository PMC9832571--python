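import logging

import pytest

from matchdem.simulate import default_scenario, generate_dataset

logging.getLogger("matchdem").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """One default-scenario dataset (flowers, nests, pollen), seed 0."""
    cfg = default_scenario(seed=0)
    return generate_dataset(cfg, seed=0)


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=0)
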