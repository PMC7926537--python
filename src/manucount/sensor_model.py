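"""Raw-sensor data model and the Earth-field-cancelling differential reading.

The wristband carries four 3-axis magnetometers on the corners of a
25 x 42 mm board, together with a 6-DoF IMU, all sampled at 52.6 Hz.
Magnetometer readings are kept in raw 16-bit LSB units throughout the
counting pipeline: the sensors span +/-4 gauss over 16 bits, so one LSB
is 8/65536 gauss (~0.122 milligauss).

The Earth's field is spatially uniform over the few centimetres of the
board, while the field of the finger-worn magnet falls off steeply with
distance.  Subtracting the reading of the magnetometer far from the ring
from the one near the ring on each side of the board, and averaging the
two sides, therefore cancels the Earth's field exactly while retaining
the ring's near-field signal.  This average is the *differential
reading*; averaging the two sides also makes the signal identical for a
device worn on either hand.

Wristband frame convention (right-handed): x along the forearm toward
the hand, y across the wrist, z dorsal.  "Near" sensors are the pair at
larger x (closer to the ring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MalformedInputError

#: Nominal sampling rate of the device, Hz.
FS_HZ = 52.6

#: Full magnetometer span is +/-4 gauss over 16 bits.
MAG_RANGE_GAUSS = 4.0
GAUSS_PER_LSB = 2.0 * MAG_RANGE_GAUSS / 65536.0  # 0.1221 mG per LSB
LSB_PER_GAUSS = 1.0 / GAUSS_PER_LSB

#: Sensor board rectangle, millimetres.  The short side runs along the
#: forearm (x), the long side across the wrist (y).
BOARD_SIDE_ALONG_MM = 25.0
BOARD_SIDE_ACROSS_MM = 42.0

_AXES = ("x", "y", "z")


def lsb_to_gauss(v):
    """Convert a raw magnetometer reading (LSB) to gauss."""
    return np.asarray(v, dtype=float) * GAUSS_PER_LSB


def gauss_to_lsb(g):
    """Convert gauss to raw LSB units (float; quantization is separate)."""
    return np.asarray(g, dtype=float) * LSB_PER_GAUSS


@dataclass(frozen=True)
class SensorFrame:
    """One time-stamped sample of all sensors.

    Attributes
    ----------
    t : float
        Time in seconds, strictly increasing across a log.
    mag : (4, 3) ndarray
        Raw magnetometer readings, LSB.
    accel : (3,) ndarray
        Accelerometer reading, g.
    gyro : (3,) ndarray
        Gyroscope reading, degrees per second.
    """

    t: float
    mag: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self):
        mag = np.asarray(self.mag, dtype=float)
        if mag.shape != (4, 3):
            raise MalformedInputError(
                f"frame at t={self.t}: expected 4x3 magnetometer block, got {mag.shape}"
            )
        object.__setattr__(self, "mag", mag)
        object.__setattr__(self, "accel", np.asarray(self.accel, dtype=float))
        object.__setattr__(self, "gyro", np.asarray(self.gyro, dtype=float))


@dataclass(frozen=True)
class DifferentialSample:
    """One 3-axis differential reading (LSB) at time ``t`` (seconds)."""

    t: float
    d: np.ndarray


@dataclass(frozen=True)
class ArrayGeometry:
    """Positions of the four magnetometers in the wristband frame (mm).

    ``left_pair`` and ``right_pair`` are ``(near, far)`` index pairs into
    ``positions``; the *near* sensor of each pair sits strictly closer to
    the ring along the hand axis (+x) than its *far* partner.
    """

    positions: np.ndarray
    left_pair: tuple[int, int] = (0, 1)
    right_pair: tuple[int, int] = (2, 3)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (4, 3):
            raise MalformedInputError("geometry needs four 3-vector positions")
        object.__setattr__(self, "positions", pos)
        for near, far in (self.left_pair, self.right_pair):
            if not pos[near, 0] > pos[far, 0]:
                raise MalformedInputError(
                    "near sensor must sit at larger x (closer to the ring) than far"
                )

    @classmethod
    def default(cls, center_mm=(-10.0, 0.0, 10.0)) -> "ArrayGeometry":
        """Board at its nominal pose: center 10 mm proximal to the wrist
        crease and 10 mm dorsal, 25 mm side along the forearm."""
        cx, cy, cz = center_mm
        hx = BOARD_SIDE_ALONG_MM / 2.0
        hy = BOARD_SIDE_ACROSS_MM / 2.0
        positions = np.array(
            [
                [cx + hx, cy - hy, cz],  # 0: near-left
                [cx - hx, cy - hy, cz],  # 1: far-left
                [cx + hx, cy + hy, cz],  # 2: near-right
                [cx - hx, cy + hy, cz],  # 3: far-right
            ]
        )
        return cls(positions=positions)

    def mirrored(self) -> "ArrayGeometry":
        """Swap the left/right pair roles (device worn on the other hand)."""
        return ArrayGeometry(
            positions=self.positions.copy(),
            left_pair=self.right_pair,
            right_pair=self.left_pair,
        )


class SensorLog:
    """Array-backed sequence of :class:`SensorFrame`.

    Stores columns as contiguous numpy arrays (``t`` shape (n,), ``mag``
    shape (n, 4, 3), ``accel``/``gyro`` shape (n, 3)) but indexes like a
    sequence of frames.
    """

    def __init__(self, t, mag, accel=None, gyro=None):
        t = np.asarray(t, dtype=float)
        mag = np.asarray(mag, dtype=float)
        n = t.shape[0]
        if mag.shape != (n, 4, 3):
            raise MalformedInputError(
                f"magnetometer block must be (n, 4, 3); got {mag.shape} for n={n}"
            )
        if np.any(np.isnan(mag)):
            bad = int(np.argwhere(np.isnan(mag).any(axis=(1, 2)))[0, 0])
            raise MalformedInputError(f"missing magnetometer channel in frame {bad}")
        if n > 1 and np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise MalformedInputError(f"time not strictly increasing at frame {bad}")
        self.t = t
        self.mag = mag
        self.accel = np.zeros((n, 3)) if accel is None else np.asarray(accel, float)
        self.gyro = np.zeros((n, 3)) if gyro is None else np.asarray(gyro, float)

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i) -> SensorFrame:
        if isinstance(i, slice):
            return SensorLog(self.t[i], self.mag[i], self.accel[i], self.gyro[i])
        return SensorFrame(
            t=float(self.t[i]), mag=self.mag[i], accel=self.accel[i], gyro=self.gyro[i]
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @classmethod
    def from_frames(cls, frames) -> "SensorLog":
        frames = list(frames)
        return cls(
            t=np.array([f.t for f in frames]),
            mag=np.stack([f.mag for f in frames]) if frames else np.empty((0, 4, 3)),
            accel=np.stack([f.accel for f in frames]) if frames else np.empty((0, 3)),
            gyro=np.stack([f.gyro for f in frames]) if frames else np.empty((0, 3)),
        )


class DifferentialLog:
    """Array-backed sequence of :class:`DifferentialSample` (LSB units)."""

    def __init__(self, t, d):
        self.t = np.asarray(t, dtype=float)
        self.d = np.asarray(d, dtype=float)
        if self.d.shape != (self.t.shape[0], 3):
            raise MalformedInputError("differential block must be (n, 3)")

    def __len__(self) -> int:
        return self.t.shape[0]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return DifferentialLog(self.t[i], self.d[i])
        return DifferentialSample(t=float(self.t[i]), d=self.d[i])

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


def _as_sensor_log(frames) -> SensorLog:
    if isinstance(frames, SensorLog):
        return frames
    return SensorLog.from_frames(frames)


def compute_differential(frames, geometry: ArrayGeometry | None = None) -> DifferentialLog:
    """Differential reading: Earth-field-free 3-axis signal, LSB.

    For each frame,
    ``d = ((mag[near_left] - mag[far_left]) + (mag[near_right] - mag[far_right])) / 2``
    componentwise.  The operation is stateless (frame k depends only on
    frame k) and exactly cancels any field common to all four sensors.
    """
    log = _as_sensor_log(frames)
    geometry = geometry if geometry is not None else ArrayGeometry.default()
    nl, fl = geometry.left_pair
    nr, fr = geometry.right_pair
    d = ((log.mag[:, nl] - log.mag[:, fl]) + (log.mag[:, nr] - log.mag[:, fr])) / 2.0
    return DifferentialLog(t=log.t, d=d)
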