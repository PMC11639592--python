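"""Sliding-window segmentation and the 14-feature bank per IMU channel.

IMU location identification happens at the start of a trial, so only the
first ten seconds of each recording feed the classifier.  Each window of 3 s
(300 samples at 100 Hz, stride 1 sample by default) yields 14 features per
channel over the 6 inertial channels (3-axis accelerometer + 3-axis
gyroscope): 12 time-domain —

    mean, standard deviation, root mean square, median, skewness, kurtosis,
    waveform length, zero crossings, slope sign changes, mean absolute
    value, interquartile range, median absolute deviation

— plus 2 frequency-domain: spectral peak frequency (Hz) and spectral peak
index (FFT bin of that peak, DC excluded).  That is 14 x 6 = 84 features per
IMU window, ordered channel-major (all 14 features of acc_x, then acc_y, ...).

Conventions for degenerate/ambiguous cases (fixed for determinism):
population (biased) moments; skewness and excess kurtosis are 0 for
zero-variance windows; zero crossings count strict sign changes of the
mean-removed signal with zeros inheriting the previous sign; slope sign
changes apply the same rule to the first difference, with no amplitude
deadband; spectral features use the one-sided FFT magnitude of the raw
(untapered) window.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataError, InvalidArgumentError
from .exercise_registry import LOCATION_CODES
from .imu_stream import ImuStream

__all__ = [
    "WindowSpec",
    "FeatureMatrix",
    "Scaler",
    "LabeledStream",
    "CHANNELS",
    "FEATURES_PER_CHANNEL",
    "feature_names",
    "count_windows",
    "extract_window_features",
    "extract_stream_features",
    "build_dataset",
    "fit_scaler",
    "apply_scaler",
    "inverse_scaler",
]

CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")

FEATURES_PER_CHANNEL = (
    "mean",
    "std",
    "rms",
    "median",
    "skewness",
    "kurtosis",
    "waveform_length",
    "zero_crossings",
    "slope_sign_changes",
    "mean_absolute_value",
    "interquartile_range",
    "median_absolute_deviation",
    "spectral_peak_freq",
    "spectral_peak_index",
)


def feature_names() -> list[str]:
    """The 84 feature names, channel-major, in extraction order."""
    return [f"{ch}__{feat}" for ch in CHANNELS for feat in FEATURES_PER_CHANNEL]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in samples (3 s / 300 samples at 100 Hz)."""

    length_samples: int = 300
    stride_samples: int = 1

    def __post_init__(self) -> None:
        if self.length_samples <= 0 or self.stride_samples <= 0:
            raise InvalidArgumentError("window length and stride must be positive")


def count_windows(n_samples: int, w: WindowSpec) -> int:
    """Number of windows in a record: floor((n - length) / stride) + 1.

    A record shorter than one window yields zero windows (with a warning),
    not an error, so corpus builders can skip it gracefully.
    """
    if n_samples < w.length_samples:
        warnings.warn(
            f"record of {n_samples} samples is shorter than the "
            f"{w.length_samples}-sample window; zero windows", stacklevel=2,
        )
        return 0
    return (n_samples - w.length_samples) // w.stride_samples + 1


@dataclass(frozen=True)
class LabeledStream:
    """An ImuStream annotated with its placement label and trial metadata."""

    stream: ImuStream
    location: str   # one of the five IMU sites
    subject: str
    exercise: str


@dataclass
class FeatureMatrix:
    """Windowed feature table with labels and grouping metadata.

    X : (n_windows, n_features) float array
    feature_names : column names, stable extraction order
    labels : (n_windows,) int location codes 1..5 (or None if unlabeled)
    groups : (n_windows,) subject ids for subject-wise splitting
    exercises : (n_windows,) exercise names
    """

    X: np.ndarray
    feature_names: list[str]
    labels: np.ndarray | None = None
    groups: np.ndarray | None = None
    exercises: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.feature_names):
            raise InvalidArgumentError("X shape does not match feature_names")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidArgumentError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.X)

    def select(self, names: Sequence[str]) -> "FeatureMatrix":
        """Column subset in the given order."""
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.X[:, idx], list(names), self.labels,
                             self.groups, self.exercises)

    def rows(self, mask: np.ndarray) -> "FeatureMatrix":
        """Row subset by boolean mask or index array."""
        return FeatureMatrix(
            self.X[mask], self.feature_names,
            None if self.labels is None else self.labels[mask],
            None if self.groups is None else self.groups[mask],
            None if self.exercises is None else self.exercises[mask],
        )

    def save(self, csv_path: str | Path) -> None:
        """Persist as CSV (header = feature names) + JSON metadata sidecar."""
        csv_path = Path(csv_path)
        pd.DataFrame(self.X, columns=self.feature_names).to_csv(csv_path, index=False)
        meta = {
            "labels": None if self.labels is None else self.labels.tolist(),
            "groups": None if self.groups is None else self.groups.tolist(),
            "exercises": None if self.exercises is None else self.exercises.tolist(),
        }
        csv_path.with_suffix(".meta.json").write_text(json.dumps(meta))


def _filled_signs(x: np.ndarray) -> np.ndarray:
    """Per-row signs with zeros replaced by the previous nonzero sign.

    Leading zeros stay zero and never count as a crossing.
    """
    s = np.sign(x)
    idx = np.where(s != 0, np.arange(x.shape[1]), 0)
    np.maximum.accumulate(idx, axis=1, out=idx)
    return np.take_along_axis(s, idx, axis=1)


def _sign_changes(x: np.ndarray) -> np.ndarray:
    s = _filled_signs(x)
    return np.sum(s[:, 1:] * s[:, :-1] < 0, axis=1).astype(float)


def _channel_features(W: np.ndarray, rate: float) -> np.ndarray:
    """All 14 features of one channel for a batch of windows (n, L) -> (n, 14)."""
    n, L = W.shape
    mean = W.mean(axis=1)
    centered = W - mean[:, None]
    var = np.mean(centered**2, axis=1)
    std = np.sqrt(var)
    rms = np.sqrt(np.mean(W**2, axis=1))
    median = np.median(W, axis=1)
    safe = np.where(std > 0.0, std, 1.0)
    m3 = np.mean(centered**3, axis=1)
    m4 = np.mean(centered**4, axis=1)
    skew = np.where(std > 0.0, m3 / safe**3, 0.0)
    kurt = np.where(std > 0.0, m4 / safe**4 - 3.0, 0.0)
    wl = np.sum(np.abs(np.diff(W, axis=1)), axis=1)
    zc = _sign_changes(centered)
    ssc = _sign_changes(np.diff(W, axis=1))
    mav = np.mean(np.abs(W), axis=1)
    q75, q25 = np.percentile(W, [75, 25], axis=1)
    iqr = q75 - q25
    mad = np.median(np.abs(W - median[:, None]), axis=1)
    mags = np.abs(np.fft.rfft(W, axis=1))
    peak_idx = np.argmax(mags[:, 1:], axis=1) + 1  # DC excluded
    peak_freq = peak_idx * rate / L
    return np.column_stack([
        mean, std, rms, median, skew, kurt, wl, zc, ssc, mav, iqr, mad,
        peak_freq, peak_idx.astype(float),
    ])


def _batch_features(wins: np.ndarray, rate: float) -> np.ndarray:
    """Features of a window batch (n, L, 6) -> (n, 84), channel-major."""
    if not np.all(np.isfinite(wins)):
        bad = np.flatnonzero(~np.all(np.isfinite(wins), axis=(1, 2)))
        raise DataError(f"non-finite samples in window(s) {bad[:5].tolist()}")
    return np.concatenate(
        [_channel_features(wins[:, :, c], rate) for c in range(wins.shape[2])],
        axis=1,
    )


def extract_window_features(window: np.ndarray, rate: float = 100.0) -> np.ndarray:
    """84-vector of one window given as a (length, 6) block in channel order."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[1] != len(CHANNELS):
        raise InvalidArgumentError(f"window must be (length, 6), got {window.shape}")
    return _batch_features(window[None], rate)[0]


def _stream_channels(s: ImuStream) -> np.ndarray:
    return np.concatenate([s.acc, s.gyr], axis=1)


def extract_stream_features(s: ImuStream, w: WindowSpec) -> np.ndarray:
    """Feature matrix of all windows of one stream, (n_windows, 84)."""
    data = _stream_channels(s)
    if count_windows(len(data), w) == 0:
        return np.empty((0, len(feature_names())))
    wins = sliding_window_view(data, w.length_samples, axis=0)  # (n, 6, L)
    wins = wins[:: w.stride_samples].transpose(0, 2, 1)
    return _batch_features(np.ascontiguousarray(wins), s.sample_rate)


def build_dataset(
    streams: Sequence[LabeledStream],
    w: WindowSpec | None = None,
    first_seconds: float = 10.0,
) -> FeatureMatrix:
    """Windowed feature matrix over a labeled stream collection.

    Only the first ``first_seconds`` of every stream are used (placement is
    identified at the start of a trial, and truncation balances exercises).
    Streams shorter than that are skipped with a warning.  Row order is
    deterministic: sorted by (subject, exercise, location), window start
    ascending within a stream.
    """
    w = w or WindowSpec()
    blocks, labels, groups, exercises = [], [], [], []
    ordered = sorted(streams, key=lambda ls: (ls.subject, ls.exercise, ls.location))
    for ls in ordered:
        s = ls.stream
        n_first = int(round(first_seconds * s.sample_rate))
        if len(s) < n_first:
            warnings.warn(
                f"stream ({ls.subject}, {ls.exercise}, {ls.location}) has "
                f"{len(s)} frames < {n_first}; skipped", stacklevel=2,
            )
            continue
        trimmed = ImuStream(s.sensor_id, s.package_numbers[:n_first],
                            s.acc[:n_first], s.gyr[:n_first], s.mag[:n_first],
                            s.sample_rate)
        F = extract_stream_features(trimmed, w)
        if ls.location not in LOCATION_CODES:
            raise InvalidArgumentError(f"unknown location label {ls.location!r}")
        blocks.append(F)
        labels.append(np.full(len(F), LOCATION_CODES[ls.location], dtype=int))
        groups.append(np.full(len(F), ls.subject, dtype=object))
        exercises.append(np.full(len(F), ls.exercise, dtype=object))
    if not blocks:
        raise DataError("no usable streams")
    return FeatureMatrix(
        X=np.concatenate(blocks),
        feature_names=feature_names(),
        labels=np.concatenate(labels),
        groups=np.concatenate(groups),
        exercises=np.concatenate(exercises),
    )


@dataclass(frozen=True)
class Scaler:
    """Per-feature standardizer to zero mean and unit (population) std."""

    mu: np.ndarray
    sigma: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mu": self.mu.tolist(),
                                          "sigma": self.sigma.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["mu"], float), np.asarray(d["sigma"], float))


def _matrix(X) -> np.ndarray:
    return np.asarray(X.X if hasattr(X, "X") else X, dtype=float)


def fit_scaler(X) -> Scaler:
    """Fit mu/sigma on (training) rows; zero-variance sigmas floored at 1e-12."""
    A = _matrix(X)
    mu = A.mean(axis=0)
    sigma = A.std(axis=0)  # population
    n_zero = int(np.sum(sigma < 1e-12))
    if n_zero:
        warnings.warn(f"{n_zero} zero-variance feature(s); sigma floored at 1e-12",
                      stacklevel=2)
    sigma = np.maximum(sigma, 1e-12)
    return Scaler(mu=mu, sigma=sigma)


def apply_scaler(X, s: Scaler):
    """Standardize: (x - mu) / sigma.  Not idempotent — apply exactly once."""
    A = (_matrix(X) - s.mu) / s.sigma
    if hasattr(X, "X"):
        return FeatureMatrix(A, X.feature_names, X.labels, X.groups, X.exercises)
    return A


def inverse_scaler(X, s: Scaler):
    """Algebraic inverse of :func:`apply_scaler`."""
    A = _matrix(X) * s.sigma + s.mu
    if hasattr(X, "X"):
        return FeatureMatrix(A, X.feature_names, X.labels, X.groups, X.exercises)
    return A
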