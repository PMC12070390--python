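import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cells():
    """Two subjects with known CSI values."""
    return pd.DataFrame({
        "subject_id": ["s1"] * 5 + ["s2"] * 4,
        "csi": [1.0, 2.0, 3.0, 4.0, 5.0, 10.0, 20.0, 30.0, 40.0],
    })


@pytest.fixture
def random_quantile_matrix(rng):
    """A 40-subject quantile matrix from lognormal cell samples."""
    from quantindex.quantiles import ProbabilityGrid, tabulate_quantiles

    frames = []
    for i in range(40):
        vals = np.exp(rng.normal(2.5 + 0.3 * rng.standard_normal(), 0.7, size=60))
        frames.append(pd.DataFrame({"subject_id": f"s{i:02d}", "csi": vals}))
    cells = pd.concat(frames, ignore_index=True)
    return tabulate_quantiles(cells, ProbabilityGrid.default(19))
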