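"""Data model and file I/O for single-sensor wrist IMU recordings.

A recording holds the tri-axial accelerometer (specific force, sensor frame,
m/s^2), tri-axial gyroscope (deg/s) and the per-sample sensor-to-global
rotation matrix delivered by the sensor's embedded orientation estimator.
The global frame has z vertical, pointing up.

The on-disk dialect is defined by this package: a comma-separated file with
one header row ``t,ax,ay,az,gx,gy,gz,r11,...,r33`` (rotation row-major), one
row per sample, plus a JSON sidecar ``<name>.meta.json`` carrying subject,
group, tested arm, ARAT item and sampling rate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: standard gravity used for gravity removal, m/s^2
G = 9.81

#: accelerometer full-scale range, m/s^2 (+-5 g sensor)
ACCEL_RANGE = 5.0 * G
#: gyroscope full-scale range, deg/s
GYRO_RANGE = 1200.0

CSV_COLUMNS = (
    "t", "ax", "ay", "az", "gx", "gy", "gz",
    "r11", "r12", "r13", "r21", "r22", "r23", "r31", "r32", "r33",
)

SECTIONS = ("Grasp", "Grip", "Pinch", "Gross")

#: ARAT item -> section membership
_SECTION_OF_ITEM = {
    **{i: "Grasp" for i in range(1, 7)},
    **{i: "Grip" for i in range(7, 11)},
    **{i: "Pinch" for i in range(11, 17)},
    **{i: "Gross" for i in range(17, 20)},
}


def section_of_item(item: int) -> str:
    """Return the ARAT section (Grasp/Grip/Pinch/Gross) an item belongs to."""
    try:
        return _SECTION_OF_ITEM[int(item)]
    except KeyError:
        raise ValueError(f"ARAT item must be in 1..19, got {item!r}") from None


@dataclass(frozen=True)
class TaskMeta:
    """Identity of one ARAT item; ``section`` is derived from ``item``."""

    item: int

    def __post_init__(self):
        section_of_item(self.item)  # validates range

    @property
    def section(self) -> str:
        return section_of_item(self.item)


@dataclass(frozen=True)
class RecordingMeta:
    """Subject/task annotations carried next to the signal streams."""

    subject: str | None = None
    group: str | None = None  # "control" | "MS" (or a severity label)
    arm: str | None = None
    item: int | None = None

    @property
    def section(self) -> str | None:
        return None if self.item is None else section_of_item(self.item)


@dataclass
class IMURecording:
    """Time-stamped IMU streams plus orientation for one ARAT task.

    Parameters
    ----------
    time : (n,) seconds, uniformly sampled, strictly increasing.
    rate : sampling rate in Hz (50 for the wrist sensor).
    accel : (n, 3) specific force in the sensor frame, m/s^2.
    gyro : (n, 3) angular velocity, deg/s.
    rot : (n, 3, 3) rotation matrices mapping sensor frame to global frame.
    meta : subject/group/arm/item annotations.
    """

    time: np.ndarray
    rate: float
    accel: np.ndarray
    gyro: np.ndarray
    rot: np.ndarray
    meta: RecordingMeta = field(default_factory=RecordingMeta)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.rot = np.asarray(self.rot, dtype=float)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    def validate(self, *, rot_tol: float = 1e-6, time_tol: float = 1e-9) -> "IMURecording":
        """Check the structural and physical invariants; return self.

        Raises
        ------
        ValidationError
            On inconsistent stream lengths, a non-uniform time base,
            non-orthonormal rotation matrices, or out-of-range samples.
        """
        n = len(self)
        if n < 2:
            raise ValidationError("recording must contain at least 2 samples")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError("accel/gyro must have shape (n, 3) matching time")
        if self.rot.shape != (n, 3, 3):
            raise ValidationError("rot must have shape (n, 3, 3) matching time")
        steps = np.diff(self.time)
        if np.any(steps <= 0):
            raise ValidationError("time must be strictly increasing")
        if np.max(np.abs(steps - self.dt)) > time_tol + 1e-12:
            raise ValidationError(
                f"non-uniform time base: step deviates from 1/rate={self.dt} "
                f"by up to {np.max(np.abs(steps - self.dt)):.3g} s"
            )
        rtr = np.einsum("nij,nik->njk", self.rot, self.rot)
        dev = np.abs(rtr - np.eye(3)).max(axis=(1, 2))
        det = np.linalg.det(self.rot)
        bad = np.nonzero((dev > rot_tol) | (np.abs(det - 1.0) > rot_tol))[0]
        if bad.size:
            raise ValidationError(
                f"non-orthonormal rotation matrices at sample indices {bad[:10].tolist()}"
                + ("..." if bad.size > 10 else "")
            )
        if np.any(np.abs(self.accel) > ACCEL_RANGE * (1 + 1e-9)):
            raise ValidationError(f"accelerometer samples exceed +-{ACCEL_RANGE:.2f} m/s^2 range")
        if np.any(np.abs(self.gyro) > GYRO_RANGE * (1 + 1e-9)):
            raise ValidationError(f"gyroscope samples exceed +-{GYRO_RANGE:.0f} deg/s range")
        return self


def sidecar_for(path: str | Path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def read_imu_csv(path: str | Path, *, meta: RecordingMeta | None = None,
                 rate: float | None = None) -> IMURecording:
    """Read one recording from the documented CSV dialect.

    The JSON sidecar, when present, supplies the metadata and the sampling
    rate and may declare alternate units (``accel_units: "g"`` or
    ``gyro_units: "rad/s"``), which are converted to the canonical m/s^2 and
    deg/s.  Without a sidecar the rate is inferred from the time column and
    ``meta``/``rate`` keyword arguments may supply the rest.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s) {missing} in {path.name}")

    accel_scale = 1.0
    gyro_scale = 1.0
    side = sidecar_for(path)
    if side.exists():
        info = json.loads(side.read_text())
        meta = meta or RecordingMeta(
            subject=info.get("subject"),
            group=info.get("group"),
            arm=info.get("arm"),
            item=info.get("item"),
        )
        rate = rate or info.get("rate")
        if info.get("accel_units", "m/s^2") == "g":
            accel_scale = G
        if info.get("gyro_units", "deg/s") == "rad/s":
            gyro_scale = 180.0 / np.pi

    time = df["t"].to_numpy(float)
    if rate is None:
        steps = np.diff(time)
        if steps.size == 0 or np.any(steps <= 0):
            raise ValidationError("cannot infer rate from a non-increasing time column")
        rate = 1.0 / float(np.median(steps))
    accel = df[["ax", "ay", "az"]].to_numpy(float) * accel_scale
    gyro = df[["gx", "gy", "gz"]].to_numpy(float) * gyro_scale
    rot = df[[f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]].to_numpy(float)
    rot = rot.reshape(-1, 3, 3)
    rec = IMURecording(time=time, rate=float(rate), accel=accel, gyro=gyro,
                       rot=rot, meta=meta or RecordingMeta())
    return rec.validate()


def write_imu_csv(rec: IMURecording, path: str | Path) -> Path:
    """Serialize a recording (>= 9 significant digits) plus its sidecar."""
    rec.validate()
    path = Path(path)
    data = np.column_stack([rec.time, rec.accel, rec.gyro, rec.rot.reshape(len(rec), 9)])
    header = ",".join(CSV_COLUMNS)
    np.savetxt(path, data, fmt="%.12g", delimiter=",", header=header, comments="")
    side = sidecar_for(path)
    side.write_text(json.dumps(
        {
            "subject": rec.meta.subject,
            "group": rec.meta.group,
            "arm": rec.meta.arm,
            "item": rec.meta.item,
            "rate": rec.rate,
            "accel_units": "m/s^2",
            "gyro_units": "deg/s",
        },
        indent=1, sort_keys=True,
    ))
    return path


def iter_cohort_dir(directory: str | Path) -> Iterator[IMURecording]:
    """Yield recordings from a directory of ``<subject>_<item>.csv`` files."""
    directory = Path(directory)
    for path in sorted(directory.glob("*.csv")):
        if path.name.endswith(".meta.json"):
            continue
        try:
            rec = read_imu_csv(path)
        except FormatError:
            logging.getLogger(__name__).warning(
                "skipping %s: not an IMU recording in the expected dialect", path.name)
            continue
        if rec.meta.subject is None or rec.meta.item is None:
            stem = path.stem
            if "_" in stem:
                subject, _, item = stem.rpartition("_")
                try:
                    rec = replace(rec, meta=replace(rec.meta, subject=subject, item=int(item)))
                except ValueError:
                    pass
        yield rec
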