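import numpy as np
import pytest

from emg2gait import (GaitTemplate, MuscleSubset, Recording, SignalChannel,
                      SimulationConfig, fit_lopo, generate_cohort,
                      preprocess_recording)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_channel(samples, fs=200.0, kind="angular_velocity", side="left",
                 label=None, units=None):
    if label is None:
        label = "L_IMU" if kind == "angular_velocity" else "LVl"
    if units is None:
        units = "deg/s" if kind == "angular_velocity" else "a.u."
    return SignalChannel(label=label, side=side, kind=kind, fs=fs,
                         samples=np.asarray(samples, float), units=units)


@pytest.fixture
def small_recording(rng):
    """A tiny raw recording: 2 EMG + 2 IMU channels with TTL and walk bounds."""
    dur = 30.0
    channels = []
    for label, side in (("LVl", "left"), ("RVl", "right")):
        n = int((dur + 0.8) * 1000)
        channels.append(make_channel(rng.standard_normal(n), fs=1000.0,
                                     kind="emg", side=side, label=label))
    for label, side in (("L_IMU", "left"), ("R_IMU", "right")):
        n = int((dur + 0.3) * 128)
        t = np.arange(n) / 128.0
        channels.append(make_channel(200 * np.sin(2 * np.pi * 0.9 * t),
                                     fs=128.0, side=side, label=label))
    return Recording(patient_id="P01", trial_id="T01", channels=channels,
                     ttl_onset_s={"emg": 0.8, "imu": 0.3},
                     ttl_offset_s={"emg": 0.8 + dur, "imu": 0.3 + dur},
                     walk_start_s=1.0, walk_end_s=26.0)


@pytest.fixture(scope="session")
def linear_cohort():
    """Small preprocessed cohort with exact linear EMG→velocity ground truth."""
    cfg = SimulationConfig(seed=101, n_patients=3, trials_per_patient=2,
                           trial_duration_s=40.0, linear_ground_truth=True,
                           emg_noise_sd=0.02, imu_noise_sd=2.0)
    trials = generate_cohort(cfg)
    prep = [preprocess_recording(t.recording) for t in trials]
    return trials, prep


@pytest.fixture(scope="session")
def linear_lopo(linear_cohort):
    _, prep = linear_cohort
    return prep, fit_lopo(prep, MuscleSubset(pairs=("Vl",)))
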