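import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from slopact import (CohortSpec, GeneratorConfig, MoodState, PreprocessConfig,
                     generate_cohort, preprocess_record)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10/6/12 cohort of 2-day records: fast but with every class usable."""
    spec = CohortSpec(
        counts={MoodState.DEP: 10, MoodState.MAN: 6, MoodState.REM: 12},
        configs={s: GeneratorConfig(n_days=2) for s in MoodState})
    return generate_cohort(spec, seed=11)


@pytest.fixture(scope="session")
def small_epochs(small_cohort):
    epochs = []
    for rec in small_cohort:
        epochs.extend(preprocess_record(rec, PreprocessConfig()))
    return epochs
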