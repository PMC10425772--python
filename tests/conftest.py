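import numpy as np
import pytest

import cropchamber as cc


@pytest.fixture(scope="session")
def quiet_config() -> cc.ChamberConfig:
    """Default chamber with all sensor noise off."""
    return cc.ChamberConfig(noise_sd=cc.NoiseSD.off())


@pytest.fixture(scope="session")
def sim_lo(quiet_config) -> cc.SimOutput:
    """Noise-free 28-day low-ammonium crop test (shared, read-only)."""
    _, crop, sol = cc.scenario("lo_nh4")
    return cc.simulate_crop_test(quiet_config, crop, sol, duration=28, seed=0)


@pytest.fixture(scope="session")
def sim_hi() -> cc.SimOutput:
    """Noise-free 28-day high-ammonium crop test (shared, read-only)."""
    _, crop, sol = cc.scenario("hi_nh4")
    cfg = cc.ChamberConfig(noise_sd=cc.NoiseSD.off())
    return cc.simulate_crop_test(cfg, crop, sol, duration=28, seed=0)


@pytest.fixture(scope="session")
def sim_exponential(quiet_config) -> cc.SimOutput:
    """Noise-free crop with no logistic ceiling: pure exponential canopy."""
    crop = cc.CropParams(mu=0.22, plai_max=np.inf)
    return cc.simulate_crop_test(quiet_config, crop, cc.default_solution(), duration=18, seed=0)
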