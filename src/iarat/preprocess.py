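"""Zero-lag filtering, angular-speed norm and gravity-free acceleration.

The segmentation signal is the Euclidean norm of the low-pass filtered
gyroscope vector, Omega(t).  Each gyro axis is smoothed with a 4th-order
zero-lag (forward-backward) Butterworth filter before the norm is taken, so
the zero-phase property holds per axis.  Linear acceleration is rotated to
the global frame with the per-sample rotation matrix and gravity (g = 9.81
m/s^2 along global +z) is subtracted; its z component is the "vertical
acceleration" used to detect the hand-table contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError, ValidationError
from .io import G, IMURecording

DEFAULT_GYRO_CUTOFF = 2.5  # Hz


@dataclass
class AngularSpeedSeries:
    """Scalar angular speed Omega(t) >= 0, deg/s."""

    time: np.ndarray
    omega: np.ndarray
    rate: float
    filtered: bool = False
    cutoff: float | None = None

    def __len__(self) -> int:
        return self.time.shape[0]


@dataclass
class FreeAccelSeries:
    """Gravity-free tri-axial acceleration in the global frame, m/s^2."""

    time: np.ndarray
    accel_global: np.ndarray
    rate: float

    @property
    def vertical(self) -> np.ndarray:
        """Global z (vertical, up) component."""
        return self.accel_global[:, 2]

    def __len__(self) -> int:
        return self.time.shape[0]


def lowpass_zero_lag(series: np.ndarray, cutoff: float, rate: float,
                     order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth low-pass filter (zero phase lag).

    The two passes square the magnitude response, so the -3 dB point of the
    one-pass design becomes a -6 dB point (amplitude ratio 0.5 at the
    cutoff).  Edges are handled by reflective padding of ``3 * order``
    samples, benign for recordings that start and end at rest.

    Parameters
    ----------
    series : (n,) or (n, k) uniformly sampled signal(s), filtered along axis 0.
    cutoff : cutoff frequency in Hz; must be below the Nyquist rate.
    rate : sampling rate, Hz.
    order : one-pass filter order (default 4).
    """
    series = np.asarray(series, dtype=float)
    nyq = rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cutoff must lie in (0, {nyq}) Hz, got {cutoff}")
    padlen = 3 * order
    if series.shape[0] <= padlen:
        raise ParameterError(
            f"series too short for edge padding: need > {padlen} samples, got {series.shape[0]}"
        )
    b, a = butter(order, cutoff / nyq)
    return filtfilt(b, a, series, axis=0, padtype="even", padlen=padlen)


def angular_speed(rec: IMURecording, cutoff: float = DEFAULT_GYRO_CUTOFF,
                  order: int = 4) -> AngularSpeedSeries:
    """Norm of the low-pass filtered gyroscope vector, deg/s.

    Filtering is applied per axis (zero lag preserved per component), then
    the Euclidean norm is taken.  Pass ``cutoff=None`` to skip filtering.
    """
    if cutoff is None:
        gyro = rec.gyro
        filtered = False
    else:
        gyro = lowpass_zero_lag(rec.gyro, cutoff, rec.rate, order)
        filtered = True
    omega = np.linalg.norm(gyro, axis=1)
    return AngularSpeedSeries(time=rec.time, omega=omega, rate=rec.rate,
                              filtered=filtered, cutoff=cutoff)


def free_acceleration(rec: IMURecording, *, rot_tol: float = 1e-6) -> FreeAccelSeries:
    """Rotate specific force to the global frame and remove gravity.

    ``a_global(t) = R(t) a_sensor(t) - (0, 0, g)``.  For a stationary sensor
    in any orientation the result is (numerically) zero.
    """
    rtr = np.einsum("nij,nik->njk", rec.rot, rec.rot)
    dev = np.abs(rtr - np.eye(3)).max()
    if dev > rot_tol:
        raise ValidationError(f"rotation matrices not orthonormal (max deviation {dev:.3g})")
    acc = np.einsum("nij,nj->ni", rec.rot, rec.accel)
    acc[:, 2] -= G
    return FreeAccelSeries(time=rec.time, accel_global=acc, rate=rec.rate)
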