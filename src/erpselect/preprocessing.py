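"""Standard ERP processing chain up to features.

standardize -> low-pass -> straight-line slope features.  Each post-stimulus
window is standardized per trial and channel, low-pass filtered (zero-phase
Butterworth), and summarized by the least-squares slopes of short overlapping
segments — one feature per (channel, segment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Union

import numpy as np
from scipy.signal import butter, filtfilt

from .core import ContinuousRun, EpochedDataset, SensorSet

logger = logging.getLogger("erpselect")

VARIANCE_FLOOR = 1e-12


@dataclass
class FeatureTable:
    """Per-trial feature matrix with a total (channel, segment) feature map."""

    matrix: np.ndarray  # trials x features
    labels: np.ndarray
    feature_map: list[tuple[str, float]]  # feature index -> (channel, seg_start_ms)
    features_per_sensor: int
    channel_names: list[str]

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def sensor_slice(self, channel: str) -> np.ndarray:
        """Column indices of the features belonging to one channel."""
        return np.asarray(
            [j for j, (ch, _) in enumerate(self.feature_map) if ch == channel],
            dtype=np.intp,
        )

    def restrict(self, sensors: SensorSet) -> "FeatureTable":
        cols = np.concatenate([self.sensor_slice(c) for c in sensors])
        return FeatureTable(
            matrix=self.matrix[:, cols],
            labels=self.labels.copy(),
            feature_map=[self.feature_map[j] for j in cols],
            features_per_sensor=self.features_per_sensor,
            channel_names=list(sensors),
        )


def standardize_epochs(data: EpochedDataset) -> EpochedDataset:
    """Zero mean, unit variance per trial and channel over the window.

    Zero-variance trial-channels are clamped (variance floor 1e-12), which
    maps constant channels to all-zero output instead of NaN.
    """
    if data.n_samples < 2:
        raise ValueError("standardization needs >= 2 samples per trial-channel")
    x = data.epochs
    mean = x.mean(axis=2, keepdims=True)
    var = x.var(axis=2, keepdims=True)
    n_clamped = int(np.sum(var < VARIANCE_FLOOR))
    if n_clamped:
        logger.warning(
            "standardize_epochs: clamped %d zero-variance trial-channel(s)",
            n_clamped,
        )
    var = np.maximum(var, VARIANCE_FLOOR)
    return replace(data, epochs=(x - mean) / np.sqrt(var), labels=data.labels.copy())


def lowpass(
    data: Union[EpochedDataset, ContinuousRun], cutoff_hz: float = 4.0,
    order: int = 5,
) -> Union[EpochedDataset, ContinuousRun]:
    """Zero-phase Butterworth low-pass along the time axis (DC gain 1)."""
    nyquist = data.sample_rate / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {nyquist} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    b, a = butter(order, cutoff_hz / nyquist)
    if isinstance(data, EpochedDataset):
        if data.n_trials == 0:
            return replace(data, epochs=data.epochs.copy(), labels=data.labels.copy())
        filtered = filtfilt(b, a, data.epochs, axis=2)
        return replace(data, epochs=filtered, labels=data.labels.copy())
    filtered = filtfilt(b, a, data.signal, axis=1)
    return replace(data, signal=filtered, events=list(data.events))


def segment_starts_ms(
    window_len_ms: float, seg_len_ms: float, seg_step_ms: float
) -> list[float]:
    """Segment start offsets that fit fully inside the window."""
    starts, start = [], 0.0
    while start + seg_len_ms <= window_len_ms + 1e-9:
        starts.append(start)
        start += seg_step_ms
    return starts


def slope_features(
    data: EpochedDataset, seg_len_ms: float = 400.0, seg_step_ms: float = 120.0
) -> FeatureTable:
    """Least-squares slope of each short segment of each channel.

    Segments of ``seg_len_ms`` start at the window start and every
    ``seg_step_ms`` thereafter while fitting fully inside the window.  Slopes
    are in amplitude units per second, so features are sample-rate invariant.
    """
    window_len = data.window_ms[1] - data.window_ms[0]
    if seg_len_ms > window_len:
        raise ValueError("segment longer than the epoch window")
    fs = data.sample_rate
    seg_n = int(round(seg_len_ms * fs / 1000.0))
    if seg_n < 2:
        raise ValueError("segments must span at least 2 samples")
    step_n = seg_step_ms * fs / 1000.0
    starts = segment_starts_ms(window_len, seg_len_ms, seg_step_ms)

    # centered time regressor in seconds; slope = sum(tc * x) / sum(tc^2)
    t = np.arange(seg_n) / fs
    tc = t - t.mean()
    denom = float(np.sum(tc**2))

    n_trials, n_ch = data.n_trials, data.n_channels
    feats = np.empty((n_trials, n_ch * len(starts)))
    feature_map: list[tuple[str, float]] = []
    for ci, ch in enumerate(data.channel_names):
        for si, start_ms in enumerate(starts):
            a = int(round(si * step_n))
            seg = data.epochs[:, ci, a : a + seg_n]
            feats[:, ci * len(starts) + si] = seg @ tc / denom
            feature_map.append((ch, data.window_ms[0] + start_ms))
    return FeatureTable(
        matrix=feats,
        labels=data.labels.copy(),
        feature_map=feature_map,
        features_per_sensor=len(starts),
        channel_names=list(data.channel_names),
    )
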