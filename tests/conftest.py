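import logging

import pytest
from hypothesis import HealthCheck, settings

from borealcarbon import LandscapeModel, generate_landscape, load_config
from borealcarbon.synthetic import noise_free

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# Silence the (intentional) negative-pool-change warnings during bulk runs.
logging.getLogger("borealcarbon").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def config():
    return load_config()


@pytest.fixture(scope="session")
def small_config():
    """A reduced landscape (19 stands) for fast pipeline tests."""
    return load_config(overrides={"synthetic": {
        "class_counts": {"initiation": 5, "young": 3, "middle_aged": 4,
                         "mature": 4, "old": 3},
        "n_clearcuts": 2,
        "n_pine": 10, "n_spruce": 9, "n_till": 12, "n_sediment": 7,
    }})


@pytest.fixture(scope="session")
def small_noise_free(small_config):
    cfg = noise_free(small_config)
    bundle, truth = generate_landscape(cfg, seed=11)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_results(small_noise_free):
    cfg, bundle, truth = small_noise_free
    return LandscapeModel(bundle, config=cfg).fit()


@pytest.fixture(scope="session")
def full_noise_free(config):
    """The full 50-stand study design, noise-free, generated and fitted."""
    cfg = noise_free(config)
    bundle, truth = generate_landscape(cfg, seed=7)
    results = LandscapeModel(bundle, config=cfg).fit()
    return cfg, bundle, truth, results


@pytest.fixture(scope="session")
def full_noisy(config):
    """The full 50-stand design with default measurement noise."""
    bundle, truth = generate_landscape(config, seed=3)
    results = LandscapeModel(bundle, config=config).fit()
    return bundle, truth, results
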