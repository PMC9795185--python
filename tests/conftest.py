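import numpy as np
import pandas as pd
import pytest

from ccakit.cutpoints import build_scoring_forms
from ccakit.simulate import SimConfig, generate_normative_sample


@pytest.fixture(scope="session")
def normative_sample() -> pd.DataFrame:
    """Mid-sized seeded cohort shared across derivation/scoring tests."""
    return generate_normative_sample(SimConfig(n_participants=2000, seed=11))


@pytest.fixture(scope="session")
def quartile_form(normative_sample):
    """Pooled 5-point quartile form derived from the shared cohort."""
    return build_scoring_forms(normative_sample, method="quartile", stratify=False)[0]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
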