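import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from semgrej.classifier import TrainConfig
from semgrej.pipeline import PipelineConfig, SplitSpec, run_pipeline
from semgrej.synthetic import SimulationConfig, default_movement_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def reduced_config(seed: int = 0) -> PipelineConfig:
    """Small but complete pipeline config: short repetitions, shallow image
    stack (T=26, the smallest the conv stack handles comfortably), fewer
    epochs.  Keeps end-to-end tests in seconds while exercising every stage.
    """
    cfg = PipelineConfig(
        simulation=SimulationConfig(repetition_s=2.0, rest_s=1.0, repetitions=6, seed=seed),
        stack=26,
        train=TrainConfig(epochs=60, seed=seed),
        seed=seed,
    )
    cfg.ae.epochs = 200
    return cfg


@pytest.fixture(scope="session")
def small_pipeline_result():
    """One trained reduced pipeline shared by rejection/evaluation tests."""
    return run_pipeline(reduced_config(seed=0))


@pytest.fixture(scope="session")
def movement_set():
    return default_movement_set()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
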