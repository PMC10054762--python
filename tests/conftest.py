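import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def depletion_means() -> pd.DataFrame:
    """Published depletion time course: mean of three replicates per stop time."""
    from microstab import datasets

    return datasets.load_depletion_means()


@pytest.fixture(scope="session")
def design():
    from microstab import StudyDesign

    return StudyDesign()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
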