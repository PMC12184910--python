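import numpy as np
import pandas as pd
import pytest

from genebuffer import state_from_t_bar


@pytest.fixture
def c1():
    """Single mutant with 70% of wild-type fitness."""
    return state_from_t_bar(0.7)


@pytest.fixture
def d1():
    """Single mutant with 50% of wild-type fitness."""
    return state_from_t_bar(0.5)


@pytest.fixture
def five_record_table():
    """Five crosses whose raw serial residuals are (0.1, -0.1, 0.2, 0, -0.2)."""
    f_query = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
    f_array = np.array([0.8, 0.8, 0.8, 0.8, 0.8])
    raw = np.array([0.1, -0.1, 0.2, 0.0, -0.2])
    return pd.DataFrame({
        "query_id": [f"Q{i}" for i in range(5)],
        "array_id": [f"A{i}" for i in range(5)],
        "f_query": f_query,
        "f_array": f_array,
        "f_double": f_query * f_array + raw,
        "sd_double": np.full(5, 0.05),
    })
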