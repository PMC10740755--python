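"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from gfblup import SimConfig, build_grm, simulate_study

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_discovery=150,
        n_target=120,
        n_snps=600,
        n_chromosomes=5,
        n_qtls=60,
        h2_trait=0.45,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def target_grm(small_study):
    return build_grm(small_study["target"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20230)
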