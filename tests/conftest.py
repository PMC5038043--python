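import numpy as np
import pandas as pd
import pytest

from plaque_signals.io_core import CountMatrix, validate_metadata


@pytest.fixture
def tiny_counts() -> CountMatrix:
    return CountMatrix(["t1", "t2"], ["s1", "s2"], np.array([[3, 0], [1, 2]]))


@pytest.fixture
def small_meta() -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3"],
            "bop": [0, 3, 6],
            "periodontitis": ["no", "no", "yes"],
            "site": ["lungwena", "malindi", "mangochi"],
            "intervention": ["IFA", "MMN", "LNS"],
            "hiv": ["no", "yes", "no"],
            "seqrun": ["run1", "run2", "run1"],
        }
    )
    return validate_metadata(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
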