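"""Sensor-signal preprocessing: relative voltage, standardization,
Savitzky-Golay smoothing, derivative channels, and sliding windows.

The pipeline order is fixed: dV/V0 -> standardize -> smooth -> derivatives
-> windowize. Standardization statistics are computed within a partition
(training and test partitions are standardized separately, so test frames
never leak into training statistics). Each emitted window is 60 time steps
x 27 channels: the 9 sensor signals followed by their first and second
derivatives, with the target angles taken at the window's last frame
(causal alignment, usable in real time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "NormalizationStats",
    "WindowBatch",
    "relative_voltage",
    "standardize",
    "smooth",
    "derivatives",
    "windowize",
    "preprocess_partition",
]

WINDOW_LENGTH = 60
SG_WINDOW = 31
SG_ORDER = 5


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean/sd and the partition they were computed from."""

    mean: np.ndarray
    sd: np.ndarray
    source: str = "train"
    floored_channels: tuple[int, ...] = ()  # zero-variance channels, sd floored


@dataclass(frozen=True)
class WindowBatch:
    """A batch of model inputs: (n, 60, 27) windows with aligned targets."""

    x: np.ndarray  # (n, win, 3 * n_sensors)
    y: np.ndarray  # (n, n_targets) degrees
    participant_id: str = ""
    speed: np.ndarray | None = None  # (n,) km/h per window
    trial_index: np.ndarray | None = None  # (n,)
    end_frame: np.ndarray | None = None  # (n,) index of each window's last frame

    def __post_init__(self) -> None:
        if self.x.ndim != 3 or self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x must be (n, win, channels) aligned with y")

    @property
    def n_windows(self) -> int:
        return self.x.shape[0]

    @staticmethod
    def concatenate(batches: list["WindowBatch"]) -> "WindowBatch":
        if not batches:
            raise ValueError("no batches to concatenate")
        return WindowBatch(
            x=np.concatenate([b.x for b in batches], axis=0),
            y=np.concatenate([b.y for b in batches], axis=0),
            participant_id=batches[0].participant_id,
            speed=np.concatenate([b.speed for b in batches]),
            trial_index=np.concatenate([b.trial_index for b in batches]),
            end_frame=np.concatenate([b.end_frame for b in batches]),
        )


def relative_voltage(series) -> np.ndarray:
    """Relative voltage change (V - V0) / V0 against the standing baseline."""
    v0 = np.asarray(series.v0, dtype=float)
    if np.any(v0 <= 0):
        raise ValueError("baseline voltages V0 must be positive")
    return (np.asarray(series.v, dtype=float) - v0) / v0


def standardize(
    x: np.ndarray, stats: NormalizationStats | None = None, source: str = "train"
) -> tuple[np.ndarray, NormalizationStats]:
    """Z-score per channel; computes stats from ``x`` itself when none given."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least two frames to standardize")
    if stats is None:
        mean = x.mean(axis=0)
        sd = x.std(axis=0)
        floored = tuple(int(i) for i in np.flatnonzero(sd < 1e-8))
        sd = np.maximum(sd, 1e-8)
        stats = NormalizationStats(mean=mean, sd=sd, source=source,
                                   floored_channels=floored)
    return (x - stats.mean) / stats.sd, stats


def smooth(x: np.ndarray, window: int = SG_WINDOW, order: int = SG_ORDER) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing per channel."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < window:
        raise ValueError(f"need at least {window} frames, got {x.shape[0]}")
    return savgol_filter(x, window_length=window, polyorder=order, axis=0)


def derivatives(x: np.ndarray, rate: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives by central differences.

    Interior frames use (x[i+1] - x[i-1]) / 2 * rate; edge frames replicate
    their nearest interior value. The second derivative applies the same
    operator to the first.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least three frames for derivatives")

    def central(v: np.ndarray) -> np.ndarray:
        d = np.empty_like(v)
        d[1:-1] = (v[2:] - v[:-2]) * (rate / 2.0)
        d[0] = d[1]
        d[-1] = d[-2]
        return d

    d1 = central(x)
    d2 = central(d1)
    return d1, d2


def windowize(
    x: np.ndarray,
    targets: np.ndarray,
    win: int = WINDOW_LENGTH,
    stride: int = 1,
    rate: float = 100.0,
    participant_id: str = "",
    speed: float = float("nan"),
    trial_index: int = -1,
) -> WindowBatch | None:
    """Cut one trial into sliding windows with derivative channels.

    ``x`` is the preprocessed (frames, n_sensors) signal of a single trial
    (windows never span trial boundaries). Each window's channels are
    ``[raw, d1, d2]`` per sensor — 27 for 9 sensors — and its target is the
    angle row at the window's last frame. Emits floor((frames - win)/stride)
    + 1 windows, or ``None`` (with a warning) for too-short trials.
    """
    x = np.asarray(x, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if x.shape[0] != targets.shape[0]:
        raise ValueError("signal and target frame counts differ")
    if x.shape[0] < win:
        warnings.warn(
            f"trial of {x.shape[0]} frames is shorter than the {win}-frame window; skipped",
            stacklevel=2,
        )
        return None
    if stride < 1:
        raise ValueError("stride must be >= 1")
    d1, d2 = derivatives(x, rate)
    feats = np.concatenate([x, d1, d2], axis=1)
    ends = np.arange(win - 1, x.shape[0], stride)
    starts = ends - win + 1
    windows = np.stack([feats[s : s + win] for s in starts], axis=0)
    return WindowBatch(
        x=windows,
        y=targets[ends],
        participant_id=participant_id,
        speed=np.full(ends.size, speed),
        trial_index=np.full(ends.size, trial_index, dtype=int),
        end_frame=ends,
    )


def preprocess_partition(
    trials: list,
    angle_trials: list,
    target_channels: tuple[int, ...] | None = None,
    stats: NormalizationStats | None = None,
    win: int = WINDOW_LENGTH,
    stride: int = 1,
    sg_window: int = SG_WINDOW,
    sg_order: int = SG_ORDER,
    rate: float = 100.0,
    source: str = "train",
) -> tuple[WindowBatch, NormalizationStats]:
    """Run the full pipeline over one partition (train or test).

    ``trials`` are :class:`~gaitstrain.synthetic.SensorSeries` and
    ``angle_trials`` the matching :class:`~gaitstrain.synthetic.JointAngleSeries`.
    Standardization statistics are computed over the partition's pooled
    relative-voltage frames unless ``stats`` is supplied; smoothing,
    derivatives and windowing are applied per trial.
    """
    if len(trials) != len(angle_trials) or not trials:
        raise ValueError("need matching, non-empty sensor and angle trial lists")
    rels = [relative_voltage(s) for s in trials]
    if stats is None:
        _, stats = standardize(np.vstack(rels), source=source)
    batches = []
    for rel, sensor, angles in zip(rels, trials, angle_trials):
        xs, _ = standardize(rel, stats)
        xs = smooth(xs, window=sg_window, order=sg_order)
        y = angles.angles
        if target_channels is not None:
            y = y[:, list(target_channels)]
        wb = windowize(
            xs,
            y,
            win=win,
            stride=stride,
            rate=rate,
            participant_id=sensor.participant_id,
            speed=sensor.speed,
            trial_index=sensor.trial_index,
        )
        if wb is not None:
            batches.append(wb)
    if not batches:
        raise ValueError("every trial was shorter than one window")
    return WindowBatch.concatenate(batches), stats
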