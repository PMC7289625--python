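import dataclasses

import pytest

from vo2verify import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration derivation-size cohort, shared across tests."""
    cfg = SimulationConfig(n_subjects=535, seed=20240101)
    tests, cohort = generate_cohort(cfg)
    return cfg, tests, cohort


@pytest.fixture()
def noiseless_config():
    """Deterministic-physiology config: no measurement or perception noise."""
    return SimulationConfig(
        n_subjects=20, seed=5, measurement_noise_sd_vo2=0.0, hr_noise_sd=0.0,
        fr_noise_sd=0.0, rpe_noise_sd=0.0, prob_submaximal_termination=0.0)


def small_config(**kw) -> SimulationConfig:
    base = dict(n_subjects=50, seed=11)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture()
def make_config():
    return lambda **kw: small_config(**kw)
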