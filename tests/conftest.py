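import numpy as np
import pytest

from survunc.datagen import ScenarioSpec, SurvivalData, make_dataset


@pytest.fixture(scope="session")
def flat_data() -> SurvivalData:
    """One realisation of the flat-hazard case-study dataset (n=400)."""
    return make_dataset(ScenarioSpec("flat", seed=20191125))


@pytest.fixture(scope="session")
def increasing_data() -> SurvivalData:
    """One realisation of the increasing-hazard case-study dataset."""
    return make_dataset(ScenarioSpec("increasing", seed=20191125))


@pytest.fixture()
def toy_data() -> SurvivalData:
    """Four subjects, three events: the hand-checkable exponential example."""
    return SurvivalData(time=np.array([1.0, 2.0, 3.0, 4.0]),
                        event=np.array([1, 1, 0, 1]))
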