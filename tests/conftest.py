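import numpy as np
import pytest
from hypothesis import settings

from adjuvant_cea import default_config
from adjuvant_cea.survival import PiecewiseWeibull, WeibullPiece

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    """The shipped base-case configuration."""
    return default_config()


@pytest.fixture(scope="session")
def rfs_surgery():
    """Two-piece relapse-free-survival model for surgery only."""
    return PiecewiseWeibull(
        [
            WeibullPiece(0.001554, 1.202, 0, 97),
            WeibullPiece(0.02754, 0.5736, 97),
        ],
        endpoint="RFS",
    )


@pytest.fixture(scope="session")
def os_surgery():
    """Two-piece overall-survival model for surgery only."""
    return PiecewiseWeibull(
        [
            WeibullPiece(0.00005097, 1.755, 0, 141),
            WeibullPiece(0.005259, 0.8171, 141),
        ],
        endpoint="OS",
    )


@pytest.fixture(scope="session")
def weekly_grid():
    return np.arange(0.0, 781.0)
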