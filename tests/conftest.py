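import pandas as pd
import pytest

from speech_coged import analysis, io_config, simulator as sim


@pytest.fixture(scope="session")
def cohort():
    """A 30+30 synthetic cohort shared by the slower statistical tests."""
    profiles, agents = sim.generate_cohort(30, 30, seed=11)
    return profiles, agents


@pytest.fixture(scope="session")
def choice_log(cohort):
    profiles, agents = cohort
    return sim.run_experiment(profiles, agents, seed=11)


@pytest.fixture(scope="session")
def familiarization_log(cohort):
    profiles, agents = cohort
    return sim.run_familiarization(profiles, agents, seed=11)


@pytest.fixture(scope="session")
def profile_frame(cohort) -> pd.DataFrame:
    profiles, _ = cohort
    return io_config.profiles_to_frame(profiles)


@pytest.fixture(scope="session")
def block_frame(choice_log) -> pd.DataFrame:
    return analysis.block_summary(choice_log)
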