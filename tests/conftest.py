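import numpy as np
import pytest

from nmfimpute import AbundanceMatrix, generate_fixture


def make_matrix(values, scale="raw", metabolite_ids=None, sample_ids=None):
    """AbundanceMatrix from a value grid; NaN cells are missing."""
    values = np.asarray(values, dtype=float)
    i, j = values.shape
    return AbundanceMatrix(
        values,
        np.isfinite(values),
        metabolite_ids or [f"m{k}" for k in range(i)],
        sample_ids or [f"s{k}" for k in range(j)],
        scale,
    )


@pytest.fixture
def small_complete():
    """Complete rank-3 40x20 fixture with mild log-scale noise."""
    return generate_fixture(40, 20, 3, noise_sd=0.01, seed=7)


@pytest.fixture
def matrix_with_nas():
    vals = np.array(
        [
            [2.0, np.nan, 4.0, 6.0],
            [1.0, 3.0, np.nan, 5.0],
            [10.0, 20.0, 30.0, 40.0],
        ]
    )
    return make_matrix(vals)
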