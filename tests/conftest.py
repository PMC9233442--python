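import warnings

import numpy as np
import pytest

from varconn import synth


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def tiny_spec(**overrides):
    """A 12-subject, short-scan study on a small grid for unit tests."""
    kw = dict(
        grid_shape=(12, 12, 10),
        n_parcels=6,
        n_blind_A=3, n_sighted_A=3, n_blind_B=3, n_sighted_B=3,
        n_vols_by_cohort={"A": 60, "B": 80},
        control_seed_parcels=(),
        region_effects=(synth.RegionEffect(3, 1.0, 0.3, 1.1, 0.5),),
        education_regions=(5,),
        rng_seed=0,
    )
    kw.update(overrides)
    return synth.SyntheticSpec(**kw)


@pytest.fixture(scope="session")
def small_spec():
    return tiny_spec()


@pytest.fixture(scope="session")
def small_study(small_spec):
    return synth.simulate_study(small_spec)


@pytest.fixture(scope="session")
def small_atlas():
    return synth.make_atlas((12, 12, 10), n_parcels=6, rng_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
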