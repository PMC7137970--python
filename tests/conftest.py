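import numpy as np
import pytest

from stemage import FeedbackConfig, ModelParams, SegregationRule


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    """Baseline rate constants (the model's default parameter set)."""
    return ModelParams()


@pytest.fixture(scope="session")
def fig3_params() -> ModelParams:
    """Feedback-free analysis parameters: faster damage accumulation (v_a = 0.1)."""
    return ModelParams(v_a=0.1)


@pytest.fixture(scope="session")
def fb_none() -> FeedbackConfig:
    return FeedbackConfig(mode="none")


@pytest.fixture(scope="session")
def fb_td() -> FeedbackConfig:
    return FeedbackConfig(mode="td_only")


@pytest.fixture(scope="session")
def fb_td_stem() -> FeedbackConfig:
    return FeedbackConfig(mode="td_stem")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260)
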