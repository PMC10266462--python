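import math
import warnings

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dmcycle import load_substituent_parameters, load_table1
from dmcycle.synthetic import StudyScenario


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def params():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_substituent_parameters()


@pytest.fixture(scope="session")
def usable_params(params):
    """Substituents with a packaged transfer free energy (12 of 13)."""
    return {
        X: r
        for X, r in params.items()
        if r.dG_transfer is not None and not math.isnan(r.dG_transfer)
    }


@pytest.fixture
def scenario_factory(usable_params):
    def make(**overrides):
        kw = dict(substituents=usable_params, seed=0)
        kw.update(overrides)
        return StudyScenario(**kw)

    return make


@pytest.fixture
def noiseless_scenario(scenario_factory):
    return scenario_factory(
        interaction_noise_sd=0.0,
        measurement_dG_sd=0.0,
        measurement_dH_sd=0.0,
        enthalpy_scatter_sd=0.0,
        itc_heat_noise_frac=0.0,
        nmr_integral_noise=0.0,
        anchor_sigma=0.0,
    )
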