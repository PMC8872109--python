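import pytest

from schoolpah.core import PAHProfile, SampleSet, species_registry
from schoolpah.synth import gen_children, gen_school_samples, scenario_from_paper, with_seed


@pytest.fixture(scope="session")
def registry():
    return species_registry()


@pytest.fixture(scope="session")
def profile_factory():
    def make(concentrations, sample_id="S1", site_id="H1", traffic_group="HT", location="indoor"):
        return PAHProfile(
            sample_id=sample_id,
            site_id=site_id,
            traffic_group=traffic_group,
            location=location,
            concentrations=concentrations,
        )

    return make


@pytest.fixture(scope="session")
def study_scenario():
    return scenario_from_paper()


@pytest.fixture(scope="session")
def study_samples(study_scenario):
    return gen_school_samples(study_scenario, seed=20240101)


@pytest.fixture(scope="session")
def study_cohort(study_scenario, study_samples):
    return gen_children(study_scenario, study_samples, seed=20240101)
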