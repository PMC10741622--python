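import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_plan():
    """A complete but fast session plan for unit tests (seconds)."""
    return (("eyes open", 20.0), ("reading", 20.0),
            ("answer 1", 40.0), ("answer 2", 20.0))


@pytest.fixture(scope="session")
def small_cohort_config(short_plan):
    from examcoh.simulate import CohortConfig

    return CohortConfig(n_per_group=2, segment_plan=short_plan, seed=11)


@pytest.fixture(scope="session")
def demo_recording(small_cohort_config):
    """One clean simulated participant on the short plan."""
    from examcoh.simulate import simulate_recording

    rec, truth = simulate_recording(small_cohort_config, 0, "experienced")
    return rec


def white_noise_epochs(n_epochs: int, n_channels: int = 2, fs: float = 256.0,
                       sd: float = 1.0, seed: int = 0, task: str = "reading"):
    """Independent white-noise EpochSet helper used across test modules."""
    from examcoh.preprocess import EpochSet

    r = np.random.default_rng(seed)
    x = r.normal(0.0, sd, size=(n_epochs, n_channels, int(fs)))
    return EpochSet(task=task, epochs=x, sampling_rate=fs)
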