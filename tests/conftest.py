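import dataclasses

import pytest

from syntopy import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset (λ=0.9 defaults), with truth."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A reduced-size configuration for fast per-test generation."""
    return SyntheticConfig(seed=7, nests_model=2, nests_mimic=2,
                           specimens_per_nest=4)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


def make_config(**overrides) -> SyntheticConfig:
    return dataclasses.replace(SyntheticConfig(), **overrides)
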