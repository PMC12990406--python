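import numpy as np
import pytest

from dwatch import (
    AcquisitionConfig,
    System,
    build_zwd_scenario,
    load_library,
    load_zwd_anchors,
    render_stream,
)


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def anchors():
    return load_zwd_anchors()


@pytest.fixture(scope="session")
def grid():
    """Quarter-minute ground-truth grid over the full 240-min run."""
    return np.arange(0.0, 240.0 + 1e-9, 0.25)


@pytest.fixture(scope="session")
def co_traces(grid):
    return build_zwd_scenario(System.CO, seed=0, grid=grid)


@pytest.fixture(scope="session")
def single_traces(grid):
    return build_zwd_scenario(System.SINGLE, seed=0, grid=grid)


@pytest.fixture(scope="session")
def small_stream(co_traces, library):
    """Low-rate noiseless positive-mode stream for exactness checks."""
    config = AcquisitionConfig(mode="pos", scan_rate_hz=0.5, duration_min=240.0,
                               noise_cv=0.0, baseline_level=0.0, seed=0)
    return render_stream(co_traces, library, config)
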