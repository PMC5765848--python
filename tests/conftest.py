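import numpy as np
import pytest

from gradsense.geometry import ExteriorDisk, HalfPlane, StripWithDisk, WindowSet


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def halfplane():
    return HalfPlane()


@pytest.fixture
def disk():
    return ExteriorDisk(R=1.0)


@pytest.fixture
def strip():
    return StripWithDisk(R=1.0, a=2.0)


@pytest.fixture
def two_windows_line():
    """Two windows a unit distance apart on the boundary line."""
    return WindowSet.on_line([0.5, -0.5], 0.1)


@pytest.fixture
def three_windows_line():
    return WindowSet.on_line([-1.0, 0.0, 1.0], 0.1)
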