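import numpy as np
import pytest

from exotirf import SimulationConfig, VesicleKinetics, simulate_movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def small_config(**kw) -> SimulationConfig:
    base = dict(
        width_px=128, height_px=128, duration_s=30.0, n_events=12, seed=7,
        bleach_fraction=0.03,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def basal_small():
    """One small basal movie shared by detection/classification tests."""
    cfg = SimulationConfig(
        width_px=128, height_px=128, duration_s=30.0, n_events=15, seed=7,
        bleach_fraction=0.03,
    )
    movie, truth, mask = simulate_movie(cfg)
    return cfg, movie, truth, mask


@pytest.fixture()
def kinetics():
    return VesicleKinetics()
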