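import pytest

import conflictdelta as cd
from conflictdelta import sat_synthesis


@pytest.fixture(scope="session")
def flanker_design():
    return cd.make_design("flanker")


@pytest.fixture(scope="session")
def small_dmc_cohort(flanker_design):
    """Four synthetic DMC flanker participants (records list), seed-fixed."""
    spec = sat_synthesis.default_participant_spec("dmc", "flanker")
    return sat_synthesis.synthesize_cohort(flanker_design, spec, 4, seed=20240901)


@pytest.fixture(scope="session")
def small_analysis_set(small_dmc_cohort):
    return cd.filter_trials(small_dmc_cohort)
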