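import numpy as np
import pytest

from saxskit import (
    CompositeModel,
    GuinierPorodParams,
    InstrumentConfig,
    NoiseModel,
    ScatteringProfile,
    composite_intensity,
    make_q_grid,
)
from saxskit.synthetic import build_concentration_model


@pytest.fixture(scope="session")
def instrument() -> InstrumentConfig:
    return InstrumentConfig()


@pytest.fixture(scope="session")
def q_grid(instrument) -> np.ndarray:
    return make_q_grid(instrument)


@pytest.fixture(scope="session")
def model60() -> CompositeModel:
    """Two-aggregate + shoulder composite of the 60 mol % published row."""
    return build_concentration_model(60)


@pytest.fixture(scope="session")
def profile60(model60, q_grid) -> ScatteringProfile:
    """Noise-free 60 mol % composite curve on the instrument grid."""
    return ScatteringProfile(
        q=q_grid, intensity=composite_intensity(model60, q_grid), concentration=60.0
    )


@pytest.fixture
def single_ggp_profile(q_grid) -> tuple[GuinierPorodParams, ScatteringProfile]:
    params = GuinierPorodParams(i0=1.0, rg=1.6, d=4.0, s=0.0)
    model = CompositeModel(ggp_components=(params,))
    return params, ScatteringProfile(
        q=q_grid, intensity=composite_intensity(model, q_grid)
    )
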