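import pandas as pd
import pytest
from hypothesis import settings

from usfold import FatMassStudy, generate_cohort, table1_default_config

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized synthetic cohort (19 men + 18 women), fixed seed."""
    return generate_cohort(table1_default_config(seed=42))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    return FatMassStudy.from_cohort(default_cohort).fit()


@pytest.fixture()
def participant_frame(default_cohort) -> pd.DataFrame:
    return default_cohort.to_dataframe()
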