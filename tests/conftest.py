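import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from iarat.io import IMURecording, RecordingMeta
from iarat.preprocess import FreeAccelSeries
from iarat.synthetic import SimulationSpec, simulate_task


@pytest.fixture(scope="session")
def spec():
    return SimulationSpec()


@pytest.fixture(scope="session")
def control_durations(spec):
    """Healthy phase-duration means used as deterministic draws."""
    return dict(spec.groups["control"].phase_duration_mean)


@pytest.fixture(scope="session")
def clean_item1(spec, control_durations):
    """Noise- and tremor-free item-1 recording at the control durations."""
    return simulate_task(spec, 1, seed=3, noise=False, tremor_amp=0.0,
                         phase_durations=control_durations)


def random_recording(rng: np.random.Generator, n: int = 24, rate: float = 50.0,
                     subject: str | None = "sub1", item: int | None = 5) -> IMURecording:
    """A structurally valid recording with random in-range samples."""
    rot = Rotation.random(n, rng).as_matrix()
    return IMURecording(
        time=np.arange(n) / rate, rate=rate,
        accel=rng.uniform(-20.0, 20.0, (n, 3)),
        gyro=rng.uniform(-500.0, 500.0, (n, 3)),
        rot=rot,
        meta=RecordingMeta(subject=subject, group="control", arm="dominant", item=item),
    ).validate()


def make_free(time: np.ndarray, accel: np.ndarray, rate: float = 50.0) -> FreeAccelSeries:
    return FreeAccelSeries(time=np.asarray(time, float),
                           accel_global=np.asarray(accel, float), rate=rate)
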