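"""Feature extraction: 42 derived signals × 10 window statistics = 420 features.

From each of the seven base streams (ST, ACCx, ACCy, ACCz, ACCnorm, EDA, BVP)
six signal variants are derived: the original, its first and second central
finite-difference derivatives, and Haar discrete-wavelet approximations at
effective rates of 4, 2 and 1 Hz.  A 60-second window slides over the session
in 0.25 s steps; each (window, signal) pair yields 10 statistics, giving a
420-column feature matrix with a binary stress / non-stress label per window.

Conventions (any consistent choice preserves the pipeline's properties):

* Derivatives are length-preserving central differences scaled by the sampling
  interval, with one-sided differences at the endpoints.
* "Haar DWT at X Hz" is the cascade of single-level Haar analysis steps,
  keeping approximation coefficients, down from the native rate to X Hz; each
  level maps adjacent pairs (a, b) → (a + b)/√2 and halves the length.
* Windows are half-open [start, start + 60); a window is labelled stress iff
  strictly more than half of its covered seconds are stress seconds (ties and
  amusement both fall to non-stress).
* Variance, standard deviation, skewness and kurtosis use population
  normalization; kurtosis is Fisher excess; zero-variance input yields
  skewness = kurtosis = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SensorRecording

WINDOW_SECONDS = 60.0
WINDOW_STEP = 0.25

BASE_STREAMS = ("ST", "ACCx", "ACCy", "ACCz", "ACCnorm", "EDA", "BVP")
VARIANT_SUFFIXES = ("", "_d1", "_d2", "_dwt_4Hz", "_dwt_2Hz", "_dwt_1Hz")
DWT_TARGET_RATES = {"_dwt_4Hz": 4.0, "_dwt_2Hz": 2.0, "_dwt_1Hz": 1.0}

#: The 42 derived-signal names, registry order (stream-major, variant-minor).
SIGNAL_REGISTRY: tuple[str, ...] = tuple(
    stream + suffix for stream in BASE_STREAMS for suffix in VARIANT_SUFFIXES
)

STAT_NAMES = (
    "mean",
    "min",
    "max",
    "median",
    "max_amplitude",
    "variance",
    "std",
    "abs_deviation",
    "kurtosis",
    "skewness",
)

#: The 420 feature-column names, signal-major / statistic-minor.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{sig}__{stat}" for sig in SIGNAL_REGISTRY for stat in STAT_NAMES
)


@dataclass
class DerivedSignal:
    name: str
    samples: np.ndarray
    effective_rate: float


@dataclass
class DerivedSignalSet:
    participant_id: int
    signals: list[DerivedSignal]

    def __post_init__(self) -> None:
        names = tuple(s.name for s in self.signals)
        if names != SIGNAL_REGISTRY:
            raise ValueError("signals must be exactly the registry, in registry order")


@dataclass
class WindowIndex:
    window_id: int
    start_time: float
    binary_label: int  # 1 = stress, 0 = non-stress

    @property
    def end_time(self) -> float:
        return self.start_time + WINDOW_SECONDS


def acc_magnitude(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Euclidean magnitude sqrt(ax² + ay² + az²) of the 3-axis accelerometer."""
    ax, ay, az = np.asarray(ax, float), np.asarray(ay, float), np.asarray(az, float)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("accelerometer axes must have equal lengths")
    return np.sqrt(ax * ax + ay * ay + az * az)


def finite_derivative(signal: np.ndarray, rate: float, order: int = 1) -> np.ndarray:
    """Central-difference derivative, one-sided at the endpoints, same length.

    ``order=2`` applies the operator twice.
    """
    x = np.asarray(signal, float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if rate <= 0:
        raise ValueError("rate must be positive")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = np.gradient(x, 1.0 / rate)
    if order == 2:
        d = np.gradient(d, 1.0 / rate)
    return d


def haar_approximation(
    signal: np.ndarray, native_rate: float, target_rate: float, name: str = ""
) -> DerivedSignal:
    """Cascaded Haar approximation coefficients down to ``target_rate``.

    Each level maps adjacent pairs (a, b) → (a + b)/√2 and halves the length
    (an odd trailing sample is dropped).  The number of levels is
    log2(native_rate / target_rate); a unit ratio is the identity.
    """
    x = np.asarray(signal, float)
    if target_rate > native_rate:
        raise ValueError("target rate must not exceed the native rate")
    ratio = native_rate / target_rate
    levels = int(round(np.log2(ratio)))
    if not np.isclose(2.0**levels, ratio):
        raise ValueError("native_rate / target_rate must be a power of two")
    out = x.copy()
    for _ in range(levels):
        n = out.size - (out.size % 2)
        out = (out[0:n:2] + out[1:n:2]) / np.sqrt(2.0)
    return DerivedSignal(name=name, samples=out, effective_rate=float(target_rate))


def derive_signals(recording: SensorRecording) -> DerivedSignalSet:
    """Produce the 42 registry signals from a six-channel recording."""
    missing = [c for c in ("ST", "ACCx", "ACCy", "ACCz", "EDA", "BVP") if c not in recording.channels]
    if missing:
        raise KeyError(f"recording is missing channels: {missing}")
    base: dict[str, tuple[np.ndarray, float]] = {}
    for name in ("ST", "ACCx", "ACCy", "ACCz", "EDA", "BVP"):
        ch = recording.channels[name]
        base[name] = (np.asarray(ch.samples, float), float(ch.sampling_rate))
    base["ACCnorm"] = (
        acc_magnitude(base["ACCx"][0], base["ACCy"][0], base["ACCz"][0]),
        base["ACCx"][1],
    )

    signals: list[DerivedSignal] = []
    for stream in BASE_STREAMS:
        x, rate = base[stream]
        for suffix in VARIANT_SUFFIXES:
            name = stream + suffix
            if suffix == "":
                signals.append(DerivedSignal(name, x, rate))
            elif suffix in ("_d1", "_d2"):
                order = 1 if suffix == "_d1" else 2
                signals.append(DerivedSignal(name, finite_derivative(x, rate, order), rate))
            else:
                signals.append(haar_approximation(x, rate, DWT_TARGET_RATES[suffix], name))
    return DerivedSignalSet(participant_id=recording.participant_id, signals=signals)


def _window_starts(session_duration: float) -> np.ndarray:
    n = int(np.floor((session_duration - WINDOW_SECONDS) / WINDOW_STEP + 1e-9)) + 1
    return np.arange(n) * WINDOW_STEP


def segment_windows(session_duration: float, labels: np.ndarray) -> list[WindowIndex]:
    """Sliding 60 s / 0.25 s-step windows with majority-stress binary labels."""
    if session_duration < WINDOW_SECONDS:
        raise ValueError("session must be at least one window (60 s) long")
    labels = np.asarray(labels)
    stress = (labels == "stress").astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(stress)])
    starts = _window_starts(session_duration)
    out = []
    for i, s in enumerate(starts):
        lo = int(np.floor(s + 1e-9))
        hi = min(int(np.ceil(s + WINDOW_SECONDS - 1e-9)), len(labels))
        n_stress = prefix[hi] - prefix[lo]
        out.append(WindowIndex(i, float(s), int(2 * n_stress > hi - lo)))
    return out


def _stat_block(W: np.ndarray) -> np.ndarray:
    """The 10 statistics along axis 1 of a (windows, samples) block."""
    m = W.mean(axis=1)
    mn = W.min(axis=1)
    mx = W.max(axis=1)
    med = np.median(W, axis=1)
    amp = np.abs(W).max(axis=1)
    d = W - m[:, None]
    d2 = d * d
    m2 = d2.mean(axis=1)
    m3 = (d2 * d).mean(axis=1)
    m4 = (d2 * d2).mean(axis=1)
    std = np.sqrt(m2)
    absdev = np.abs(d).mean(axis=1)
    # zero-variance convention: skewness and kurtosis are 0 (relative tolerance
    # so that numerically-constant windows do not explode)
    tiny = 1e-24 * np.maximum(amp, 1.0) ** 2
    ok = m2 > tiny
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, m3 / np.power(m2, 1.5, where=ok, out=np.ones_like(m2)), 0.0)
        kurt = np.where(ok, m4 / np.square(np.where(ok, m2, 1.0)) - 3.0, 0.0)
    return np.column_stack([m, mn, mx, med, amp, m2, std, absdev, kurt, skew])


def window_statistics(samples: np.ndarray) -> np.ndarray:
    """The 10 statistics of one sample window, in STAT_NAMES order."""
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("cannot compute statistics of an empty window")
    return _stat_block(x[None, :])[0]


def _sliding_stats(
    x: np.ndarray, rate: float, starts: np.ndarray, chunk_elems: int = 8_000_000
) -> np.ndarray:
    """10 statistics for every window of ``x``; windows are [start, start+60)."""
    L = int(round(WINDOW_SECONDS * rate))
    idx = np.ceil(starts * rate - 1e-9).astype(np.int64)
    if idx[-1] + L > x.size:
        raise ValueError(
            f"signal too short for the window grid ({x.size} samples at {rate} Hz)"
        )
    view = np.lib.stride_tricks.sliding_window_view(x, L)
    out = np.empty((starts.size, len(STAT_NAMES)))
    step = max(1, chunk_elems // L)
    for a in range(0, starts.size, step):
        b = min(a + step, starts.size)
        out[a:b] = _stat_block(view[idx[a:b]])
    return out


def build_feature_matrix(recording: SensorRecording) -> pd.DataFrame:
    """Windows × 420 feature matrix with ``label`` and ``participant`` columns.

    Rows are ordered by window start; the index is the window id and the
    window start times are kept in ``df.attrs["window_starts"]``.  ``label``
    is 1 for stress windows, 0 for non-stress.
    """
    duration = recording.duration
    windows = segment_windows(duration, recording.labels)
    starts = np.array([w.start_time for w in windows])
    sigset = derive_signals(recording)
    blocks = [
        _sliding_stats(sig.samples, sig.effective_rate, starts) for sig in sigset.signals
    ]
    df = pd.DataFrame(
        np.concatenate(blocks, axis=1),
        columns=list(FEATURE_COLUMNS),
        index=pd.RangeIndex(len(windows), name="window_id"),
    )
    df["label"] = np.array([w.binary_label for w in windows], dtype=np.int64)
    df["participant"] = np.int64(recording.participant_id)
    df.attrs["window_starts"] = tuple(starts.tolist())
    return df


def feature_values(df: pd.DataFrame) -> np.ndarray:
    """The 420 feature columns of a feature matrix as a float array."""
    return df[list(FEATURE_COLUMNS)].to_numpy(float)
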