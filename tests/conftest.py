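import numpy as np
import pytest

from amhbridge import PairedMeasurements


@pytest.fixture
def three_point_data():
    """The hand-computable 3-point dataset: slopes {1, 1.5, 2}."""
    return PairedMeasurements(x=[1.0, 2.0, 3.0], y=[1.0, 2.0, 4.0])


@pytest.fixture
def identity_data():
    """y = x exactly, n = 12, spread over the AMH working range."""
    x = np.linspace(0.1, 20.0, 12)
    return PairedMeasurements(x=x, y=x.copy(), assay_x="a", assay_y="b")


@pytest.fixture
def noisy_line_data():
    """A seeded homoscedastic line for generic fitting tests."""
    rng = np.random.default_rng(11)
    x = rng.uniform(0.5, 15.0, 60)
    y = 0.3 + 1.1 * x + rng.normal(0.0, 0.25, 60)
    return PairedMeasurements(x=x, y=y, assay_x="src", assay_y="tgt")
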