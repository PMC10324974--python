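import numpy as np
import pytest

from stridepower import imu_processing as imu
from stridepower.synthetic import SyntheticTrialConfig, generate_trial


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free, jitter-free level trial: every stride is identical."""
    cfg = SyntheticTrialConfig(speed=3.0, grade=0.0, duration=20.0, seed=5,
                               noise_sd_accel=0.0, noise_sd_gyro=0.0,
                               step_variability=0.0)
    return generate_trial(cfg)


@pytest.fixture(scope="session")
def clean_trial_processed(clean_trial):
    """Calibrated left-foot signals with cycles, fsa and foot velocity."""
    filt = imu.lowpass_imu(clean_trial.imu_left)
    R = imu.functional_calibration(filt)
    cal = imu.apply_calibration(filt, R)
    cycles = imu.segment_cycles(
        cal, skip_seconds=clean_trial.config.static_duration)
    fsa = imu.foot_orientation_and_fsa(cal, cycles)
    vf, valid = imu.foot_velocity(cal, cycles)
    return {"cal": cal, "cycles": cycles, "fsa": fsa, "vf": vf, "valid": valid,
            "R": R, "trial": clean_trial}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
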