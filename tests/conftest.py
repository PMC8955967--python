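import pytest

from circsponge import (
    DesignParams,
    FixtureSpec,
    MIR21,
    assemble_insert,
    generate_decoy_panel,
)


@pytest.fixture(scope="session")
def mir21():
    return MIR21


@pytest.fixture(scope="session")
def default_params():
    return DesignParams()


@pytest.fixture(scope="session")
def default_construct(mir21, default_params):
    return assemble_insert(mir21, default_params)


@pytest.fixture(scope="session")
def decoy_panel(mir21):
    # seed 42 recorded as a panel that passes all validator checks
    return generate_decoy_panel(FixtureSpec(n_mirnas=20, rng_seed=42), mir21)
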