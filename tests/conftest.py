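import numpy as np
import pandas as pd
import pytest

from scanprof import ModelSpec, default_truth, generate_encounters
from scanprof.models import fit as fit_model


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Study-like synthetic cohort, desk scale."""
    return generate_encounters(default_truth(5000, seed=13))


@pytest.fixture(scope="session")
def zinb_fit_small(small_cohort):
    f = fit_model(ModelSpec("zinb"), small_cohort)
    assert f.converged
    return f


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230517)
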