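import numpy as np
import pytest

from cvltcurve import ModelParams, RecallSeries, evaluate_model
from cvltcurve.reference_data import GROUP_TRIAL_MEANS


@pytest.fixture
def healthy_all_series() -> RecallSeries:
    """Averaged recall curve of the whole healthy group."""
    return RecallSeries.from_counts(GROUP_TRIAL_MEANS["healthy_all"])


@pytest.fixture
def noiseless_series() -> tuple[ModelParams, RecallSeries]:
    """A series generated exactly by the model (no noise, no rounding)."""
    params = ModelParams(0.7, 6.0, 14.0)
    x = np.arange(1, 6, dtype=float)
    return params, RecallSeries(x, evaluate_model(params, x))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
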