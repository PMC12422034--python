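import pytest

from intecost.money import default_economy
from intecost.provider import compute_provider_costs
from intecost.synthetic import default_trial_config, generate_trial


@pytest.fixture(scope="session")
def economy():
    return default_economy()


@pytest.fixture(scope="session")
def small_config():
    return default_trial_config(n_participants=800, n_facilities_per_arm=2)


@pytest.fixture(scope="session")
def small_trial(small_config, economy):
    return generate_trial(small_config, seed=42, economy=economy)


@pytest.fixture(scope="session")
def provider_costs(small_trial, economy):
    return compute_provider_costs(
        small_trial.participants,
        small_trial.visits,
        small_trial.dispensing,
        small_trial.ledgers,
        economy,
    )


@pytest.fixture(scope="session")
def degenerate_config():
    """All sds zero: every generated component equals its mean exactly."""
    cfg = default_trial_config(
        n_participants=300, n_facilities_per_arm=2,
        facility_cv=0.0, ingredient_cv=0.0, patient_cv=0.0,
    )
    for cc in cfg.countries.values():
        for targets in cc.patient_targets.values():
            for name, dist in list(targets.items()):
                targets[name] = type(dist)(dist.mean, 0.0)
    return cfg


@pytest.fixture(scope="session")
def degenerate_trial(degenerate_config, economy):
    return generate_trial(degenerate_config, seed=7, economy=economy)
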