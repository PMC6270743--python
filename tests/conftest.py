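import numpy as np
import pytest

from fretwav.decay_model import (
    ExponentialComponents,
    FretDecayParams,
    GaussianDistanceDistribution,
    TimeGrid,
)


@pytest.fixture(scope="session")
def grid_full() -> TimeGrid:
    """Full 50 ns / 16 ps acquisition grid."""
    return TimeGrid(0.016, 3125)


@pytest.fixture(scope="session")
def grid_short() -> TimeGrid:
    """Shorter 20 ns grid for fast fitting tests."""
    return TimeGrid(0.016, 1250)


@pytest.fixture(scope="session")
def donor_components() -> ExponentialComponents:
    return ExponentialComponents((0.91, 0.09), (4.09, 1.52))


@pytest.fixture()
def low_fret_params(donor_components) -> FretDecayParams:
    """60 A / 6 A / 20% donor-only reference parameter set."""
    return FretDecayParams(
        donor_components=donor_components,
        distance=GaussianDistanceDistribution(60.0, 6.0),
        forster_radius=53.6,
        donor_only_fraction=0.2,
        peak_amplitude=1.0e4,
        background=20.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    """Fresh deterministic generator per test (no cross-test coupling)."""
    return np.random.default_rng(1234)
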