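import warnings

import numpy as np
import pytest

from rlddm import GenerativeConfig, TaskConfig, generate_cohort, RLDDM

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_multidrug_cohort():
    """Six subjects x three drugs at the default task size."""
    gen = GenerativeConfig(n_subjects=6)
    return gen, generate_cohort(gen, TaskConfig(), seed=42)


@pytest.fixture(scope="session")
def small_single_cohort():
    """Eight subjects, placebo only, 40 test trials each."""
    task = TaskConfig(n_blocks=10)
    gen = GenerativeConfig(n_subjects=8, drugs=("placebo",), drug_shifts={})
    return gen, task, generate_cohort(gen, task, seed=7)


@pytest.fixture(scope="session")
def smoke_fit(small_multidrug_cohort):
    """One cheap multi-drug model-4 fit shared across analysis tests."""
    _, df = small_multidrug_cohort
    return RLDDM(df, spec=4).fit(profile="smoke", seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
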