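"""9-axis IMU stream model and I/O.

A stream is one sensor's sequence of time-stamped frames, each carrying a
sequentially increasing package number used for inter-sensor synchronization
and Bluetooth loss detection.  Canonical internal units are m/s^2 (acc),
rad/s (gyr) and microtesla-nominal (mag); file readers convert declared units.

Both sensors reset their package counters to zero when they connect, so
two-sensor alignment is by package number, not wall clock.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, InsufficientDataError, SchemaError

__all__ = [
    "ImuFrame",
    "ImuStream",
    "GyroBias",
    "read_stream",
    "write_stream",
    "repair_stream",
    "align_streams",
    "estimate_gyro_bias",
    "subtract_bias",
]

COLUMNS = [
    "package_number",
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
]

#: Gaps longer than this many frames (1 s at 100 Hz) abort repair instead of
#: silently duplicating: such dropouts invalidate downstream sensor fusion.
DEFAULT_MAX_GAP = 100


@dataclass(frozen=True)
class ImuFrame:
    """One 9-axis sample: package number plus acc/gyr/mag 3-vectors."""

    package_number: int
    acc: np.ndarray  # m/s^2
    gyr: np.ndarray  # rad/s
    mag: np.ndarray  # uT (nominal)


@dataclass
class ImuStream:
    """One sensor's ordered 9-axis sample sequence (struct-of-arrays).

    Attributes
    ----------
    sensor_id : str
    sample_rate : float
        Nominal rate in Hz (100 for the target hardware).
    package_numbers : (n,) int array
    acc, gyr, mag : (n, 3) float arrays
    """

    sensor_id: str
    package_numbers: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray
    mag: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self) -> None:
        self.package_numbers = np.asarray(self.package_numbers, dtype=np.int64)
        for name in ("acc", "gyr", "mag"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise DataError(f"{name} must be (n, 3), got {a.shape}")
            if not np.all(np.isfinite(a)):
                raise DataError(f"non-finite values in {name}")
            setattr(self, name, a)
        n = len(self.package_numbers)
        if n == 0:
            raise DataError("empty stream")
        if not (len(self.acc) == len(self.gyr) == len(self.mag) == n):
            raise DataError("field lengths disagree")
        if np.any(self.package_numbers < 0):
            raise DataError("negative package numbers")

    def __len__(self) -> int:
        return len(self.package_numbers)

    def __getitem__(self, i: int) -> ImuFrame:
        return ImuFrame(int(self.package_numbers[i]), self.acc[i], self.gyr[i], self.mag[i])

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate

    @property
    def t(self) -> np.ndarray:
        """Time axis in seconds, frame 0 at t = 0."""
        return np.arange(len(self)) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        data = np.column_stack([self.package_numbers, self.acc, self.gyr, self.mag])
        df = pd.DataFrame(data, columns=COLUMNS)
        df["package_number"] = df["package_number"].astype(np.int64)
        return df


@dataclass(frozen=True)
class GyroBias:
    """Static gyroscope bias estimate, rad/s per axis."""

    bias: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bias, dtype=float)
        if b.shape != (3,) or not np.all(np.isfinite(b)):
            raise DataError("bias must be a finite 3-vector")
        object.__setattr__(self, "bias", b)
        if np.linalg.norm(b) > 0.1:
            warnings.warn(
                f"gyro bias magnitude {np.linalg.norm(b):.3f} rad/s is implausibly "
                "large for a consumer MEMS gyro", stacklevel=3,
            )


def read_stream(
    path: str | Path,
    format: str = "csv",
    sensor_id: str | None = None,
    sample_rate: float = 100.0,
    gyro_units: str = "rad/s",
) -> ImuStream:
    """Read one sensor's stream from CSV or JSONL.

    Parameters
    ----------
    gyro_units : {"rad/s", "deg/s"}
        Unit declared for the gyroscope columns; deg/s is converted on read.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "jsonl":
        df = pd.read_json(path, lines=True)
    else:
        raise SchemaError(f"unknown format {format!r} (expected 'csv' or 'jsonl')")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    pkg = df["package_number"].to_numpy()
    if np.any(np.diff(pkg) <= 0):
        raise DataError(f"{path.name}: package numbers are not strictly increasing")
    gyr = df[["gyr_x", "gyr_y", "gyr_z"]].to_numpy(dtype=float)
    if gyro_units == "deg/s":
        gyr = np.radians(gyr)
    elif gyro_units != "rad/s":
        raise SchemaError(f"unknown gyro_units {gyro_units!r}")
    return ImuStream(
        sensor_id=sensor_id or path.stem,
        package_numbers=pkg,
        acc=df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float),
        gyr=gyr,
        mag=df[["mag_x", "mag_y", "mag_z"]].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


def write_stream(path: str | Path, s: ImuStream, format: str = "csv") -> None:
    """Write a stream as CSV or JSONL with the canonical column schema."""
    path = Path(path)
    df = s.to_frame()
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w") as fh:
            for rec in df.to_dict(orient="records"):
                rec["package_number"] = int(rec["package_number"])
                fh.write(json.dumps(rec) + "\n")
    else:
        raise SchemaError(f"unknown format {format!r}")


def repair_stream(s: ImuStream, max_gap: int = DEFAULT_MAX_GAP) -> tuple[ImuStream, int]:
    """Fill Bluetooth losses by repeating the immediately preceding frame.

    A package number not adjacent to its predecessor indicates one or several
    lost frames; each is replaced by a copy of the last received frame.  The
    output numbering is consecutive from the first observed package number.

    Returns the repaired stream and the number of interpolated frames.

    Raises
    ------
    DataError
        On duplicate/non-monotone package numbers or a gap wider than
        ``max_gap`` frames.
    """
    pkg = s.package_numbers
    d = np.diff(pkg)
    if np.any(d == 0):
        raise DataError("duplicate package numbers")
    if np.any(d < 0):
        raise DataError("package numbers are not strictly increasing")
    if np.any(d > max_gap + 1):
        raise DataError(
            f"gap of {int(d.max()) - 1} frames exceeds max_gap={max_gap}; "
            "dropout too long to interpolate"
        )
    n_missing = int(pkg[-1] - pkg[0] + 1 - len(pkg))
    if n_missing == 0:
        return s, 0
    # index of the most recent received frame for every output slot
    full = np.arange(pkg[0], pkg[-1] + 1)
    src = np.searchsorted(pkg, full, side="right") - 1
    out = ImuStream(
        sensor_id=s.sensor_id,
        package_numbers=full,
        acc=s.acc[src],
        gyr=s.gyr[src],
        mag=s.mag[src],
        sample_rate=s.sample_rate,
    )
    return out, n_missing


def align_streams(a: ImuStream, b: ImuStream) -> tuple[ImuStream, ImuStream]:
    """Trim two repaired streams to their common package-number range."""
    lo = max(a.package_numbers[0], b.package_numbers[0])
    hi = min(a.package_numbers[-1], b.package_numbers[-1])
    if hi < lo:
        raise DataError("streams share no package-number range")

    def _cut(s: ImuStream) -> ImuStream:
        i0 = int(lo - s.package_numbers[0])
        i1 = int(hi - s.package_numbers[0]) + 1
        return ImuStream(s.sensor_id, s.package_numbers[i0:i1], s.acc[i0:i1],
                         s.gyr[i0:i1], s.mag[i0:i1], s.sample_rate)

    return _cut(a), _cut(b)


def estimate_gyro_bias(s: ImuStream, window_s: float = 10.0) -> GyroBias:
    """Mean gyroscope reading over an initial stationary window.

    Emulates the table-rest calibration: the sensor lies still and the
    per-axis mean over ``window_s`` seconds is the bias.  Warns if the
    window does not look stationary (RMS after mean removal > 0.02 rad/s).
    """
    n = int(round(window_s * s.sample_rate))
    if len(s) < n:
        raise InsufficientDataError(
            f"stream has {len(s)} frames, need {n} for a {window_s:g} s bias window"
        )
    g = s.gyr[:n]
    mean = g.mean(axis=0)
    rms = float(np.sqrt(np.mean(np.sum((g - mean) ** 2, axis=1))))
    if rms > 0.02:
        warnings.warn(
            f"gyro RMS {rms:.4f} rad/s over the bias window; sensor may not be "
            "stationary", stacklevel=2,
        )
    return GyroBias(mean)


def subtract_bias(s: ImuStream, b: GyroBias) -> ImuStream:
    """Return a copy with ``gyr - bias``; acc and mag untouched."""
    return ImuStream(s.sensor_id, s.package_numbers.copy(), s.acc.copy(),
                     s.gyr - b.bias, s.mag.copy(), s.sample_rate)
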