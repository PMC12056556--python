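import numpy as np
import pytest

from reefhdr import Observation, prepare_groups, simulate_dataset
from reefhdr.simulate import SimulationScenario


def make_obs(study="s1", site="A", date="2020-01-01", sub="ctx", het=1.0,
             facet="substrate_3d_amount", response=5.0, metric="richness",
             group="microinvertebrates", plot="p1", **kw):
    return Observation(
        study_id=study, plot_id=plot, site=site, date=date,
        substrate_context=sub, het_raw=het, het_metric="rugosity",
        facet=facet, response_value=response, response_metric=metric,
        organismal_group=group, **kw,
    )


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture(scope="session")
def small_scenario():
    """A quick, fully stochastic scenario used across suite/sensitivity tests."""
    return SimulationScenario(seed=11, n_studies=12, hdrs_per_study=6,
                              levels_per_hdr=5, reps_per_level=2)


@pytest.fixture(scope="session")
def small_groups(small_scenario):
    obs, _ = simulate_dataset(small_scenario)
    groups, _ = prepare_groups(obs)
    return groups


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
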