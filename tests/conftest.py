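import numpy as np
import pandas as pd
import pytest

from cogmsm.panel import CohortPanel


def make_panel(rows):
    """Panel from (subject_id, wave, age, state) tuples plus optional covariates."""
    cols = ["subject_id", "wave", "age", "state"]
    return CohortPanel(pd.DataFrame(rows, columns=cols[: len(rows[0])]))


@pytest.fixture
def small_panel():
    return make_panel([
        ("a", 1, 60.5, "CN"), ("a", 2, 64.5, "CN"), ("a", 3, 68.5, "MCI"),
        ("b", 1, 61.0, "CN"), ("b", 2, 65.0, "DEATH"),
        ("c", 1, 62.0, "CN"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
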