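import pytest

import coraloptics as co


@pytest.fixture(scope="session")
def default_profiles():
    return co.species_fixture()


@pytest.fixture(scope="session")
def classified_profiles(default_profiles):
    return co.classify_scattering_group(default_profiles)


@pytest.fixture(scope="session")
def groups(classified_profiles):
    return {p.species: p.group.value for p in classified_profiles}


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic experiment (seed 0), shared read-only."""
    return co.generate_experiment(co.default_config(seed=0))


@pytest.fixture()
def noiseless_config():
    cfg = co.default_config(seed=0)
    for k in cfg.noise_sd:
        cfg.noise_sd[k] = 0.0
    for k in cfg.colony_sd:
        cfg.colony_sd[k] = 0.0
    cfg.chla_decay_heterogeneity_sd = 0.0
    return cfg


from hypothesis import HealthCheck, settings as _hyp_settings

_hyp_settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.differing_executors]
)
_hyp_settings.load_profile("repro")
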