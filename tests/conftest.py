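import numpy as np
import pytest

from panmoiety import (
    SyntheticSpec,
    generate_compounds,
    generate_kinome,
    load_moiety_dictionary,
    simulate_bioactivity,
)


@pytest.fixture(scope="session")
def dictionary():
    return load_moiety_dictionary()


@pytest.fixture(scope="session")
def saturated_spec():
    """Small saturated, noise-free study: activity == OR of planted drivers."""
    return SyntheticSpec.with_default_drivers(
        n_common=2,
        n_group=1,
        n_specific=2,
        n_groups=2,
        families_per_group=2,
        kinases_per_family=(2, 3),
        n_compounds=150,
        n_features=30,
        background_prevalence=0.25,
        driver_effect=100.0,
        intercept=-50.0,
        label_noise=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def saturated_world(saturated_spec):
    catalog = generate_kinome(saturated_spec)
    features = generate_compounds(saturated_spec)
    records = simulate_bioactivity(catalog, features, saturated_spec)
    return catalog, features, records


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
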