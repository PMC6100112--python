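import pytest

from hmucall import simdata


@pytest.fixture(scope="session")
def site1_model():
    return simdata.preset("ODN1_site1")


@pytest.fixture(scope="session")
def odn1():
    """ODN1 reference + truth profile, fixed seed."""
    return simdata.make_odn("ODN1", seed=1)


@pytest.fixture(scope="session")
def odn1_experiment(odn1, site1_model):
    """Moderate-depth triplicate ODN1 experiment with matched control."""
    records, profile = odn1
    return simdata.simulate_experiment(
        records, profile, site1_model, depth=1000, replicates=3, seed=7
    )
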