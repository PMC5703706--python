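import numpy as np
import pytest

import lagflow as lf


@pytest.fixture(scope="session")
def truth():
    return lf.default_ground_truth()


@pytest.fixture(scope="session")
def truth_on_grid():
    return lf.default_ground_truth(on_grid=True)


@pytest.fixture(scope="session")
def slfo():
    return lf.generate_slfo(360.0, 0.1, (0.008, 0.07), seed=42)


def make_series(data, dt=0.5, mask=None, **kw):
    data = np.asarray(data, float)
    if data.ndim == 2:  # (voxels, t) -> line of voxels
        data = data[:, None, None, :]
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return lf.BoldSeries(
        data=data, sampling_interval=dt, affine=np.eye(4), mask=mask, **kw
    )


@pytest.fixture(scope="session")
def make_bold():
    return make_series
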