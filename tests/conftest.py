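import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from asekit import datasets
from asekit import synthetic_cohort as sc

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    return sc.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    """One simulated cohort at study defaults, shared across tests."""
    return sc.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = sc.SimulationConfig(seed=2, sigma_gdna=0.0, sigma_cdna=0.0)
    return cfg, sc.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def demo():
    return datasets.demo_cohort()


def hwe_genotypes(rng, p11, p10, p01, p00, n):
    """Draw unphased two-locus genotypes from haplotype frequencies."""
    probs = np.array([p11, p10, p01, p00], dtype=float)
    probs = probs / probs.sum()
    haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    picks = rng.choice(4, size=(n, 2), p=probs)
    g = haps[picks[:, 0]] + haps[picks[:, 1]]
    return g[:, 0], g[:, 1]
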