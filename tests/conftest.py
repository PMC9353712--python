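import numpy as np
import pandas as pd
import pytest

from rhythmlayers.core import SamplingDesign, TimeCourseMatrix
from rhythmlayers.rhythm import reference_waveforms


@pytest.fixture(scope="session")
def design():
    return SamplingDesign()


@pytest.fixture(scope="session")
def refs(design):
    """Default deduplicated reference set for the 8x3h design."""
    return reference_waveforms(design)


@pytest.fixture()
def cosine_matrix(design):
    """500 noisy cosinor genes at amplitude/noise = 3 with known phases."""
    rng = np.random.default_rng(42)
    n = 500
    phases = rng.uniform(0, 24, n)
    times = design.sample_times
    y = np.maximum(
        0.0,
        10 + 3 * np.cos(2 * np.pi * (times[None, :] - phases[:, None]) / 24)
        + rng.normal(0, 1, (n, times.shape[0])),
    )
    m = TimeCourseMatrix(
        pd.DataFrame(y, index=[f"g{i:03d}" for i in range(n)], columns=design.sample_labels),
        times,
    )
    return m, phases


def circular_lag_error(lag, phase, period=24.0):
    d = np.abs(np.asarray(lag) - np.asarray(phase)) % period
    return np.minimum(d, period - d)
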