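import numpy as np
import pytest

from multitrap import DetectionParams, LayoutSpec


@pytest.fixture
def possum_params() -> DetectionParams:
    return DetectionParams(g0=0.05, sigma=63.0)


@pytest.fixture
def small_layout() -> LayoutSpec:
    """A 20 x 10 trap grid at possum spacings, small enough for fast
    Monte-Carlo tests; buffered_area matches the exact geometry."""
    layout = LayoutSpec(
        trap_spacing=50.0,
        line_spacing=100.0,
        traps_per_line=20,
        n_lines=10,
        buffer=100.0,
        buffered_area=1.0,  # placeholder, replaced below
    )
    return LayoutSpec(
        trap_spacing=50.0,
        line_spacing=100.0,
        traps_per_line=20,
        n_lines=10,
        buffer=100.0,
        buffered_area=layout.geometric_buffered_area_ha,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20150317)
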