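import numpy as np
import pandas as pd
import pytest

from lakeso.synthetic import LakeScenario, StructuralTruth, gen_structural_dataset


@pytest.fixture(scope="session")
def quiet_scenario() -> LakeScenario:
    """Noise-free scenario: generator output is exactly the deterministic
    physical shape, so detector closure can be asserted tightly."""
    return LakeScenario(noise_sd_temp=0.0, noise_sd_chla=0.0, peak_jitter_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def truth() -> StructuralTruth:
    return StructuralTruth(seed=0)


@pytest.fixture(scope="session")
def structural_data(truth) -> pd.DataFrame:
    """A study-sized (66-event) draw from the default structural model."""
    return gen_structural_dataset(truth)


@pytest.fixture(scope="session")
def large_structural_data() -> pd.DataFrame:
    return gen_structural_dataset(StructuralTruth(n_events=5000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
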