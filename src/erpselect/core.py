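"""Domain types and dataset-bundle I/O for multichannel oddball ERP recordings.

The package's native on-disk format is a *dataset bundle*: a directory with a
``metadata.json`` describing every run, plus per run one raw float32 signal
matrix (row-major, channels x samples) and one tab-separated event table
(``onset_sample``, ``stimulus_class``).  The format is deliberately
language-neutral; anything that can read JSON, TSV and flat binary can consume
it.

Time conventions used throughout the package: sample indices are 0-based,
epoch windows are half-open ``[start_ms, end_ms)`` relative to stimulus onset,
and the event onset sample maps to epoch sample 0 when ``start_ms == 0``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

logger = logging.getLogger("erpselect")

STANDARD = "standard"
TARGET = "target"
STIMULUS_CLASSES = (STANDARD, TARGET)

BUNDLE_METADATA = "metadata.json"
_BUNDLE_FORMAT = "erpselect-bundle"


class BundleFormatError(ValueError):
    """A dataset bundle is missing or has an inconsistent field."""


@dataclass(frozen=True)
class SensorSet:
    """An ordered, duplicate-free subset of channel identifiers."""

    members: tuple[str, ...]

    def __init__(self, members: Iterable[str]):
        members = tuple(members)
        if len(set(members)) != len(members):
            raise ValueError(f"duplicate channels in sensor set: {members}")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(self.members)

    def __contains__(self, channel: str) -> bool:
        return channel in self.members

    def without(self, channel: str) -> "SensorSet":
        if channel not in self.members:
            raise ValueError(f"channel {channel!r} not in sensor set")
        return SensorSet(c for c in self.members if c != channel)

    def issubset(self, other: Union["SensorSet", Sequence[str]]) -> bool:
        return set(self.members) <= set(other)

    def indices_in(self, channel_names: Sequence[str]) -> np.ndarray:
        """Positions of this set's members within a full channel list."""
        lookup = {name: i for i, name in enumerate(channel_names)}
        missing = [c for c in self.members if c not in lookup]
        if missing:
            raise KeyError(f"unknown channel(s): {missing}")
        return np.asarray([lookup[c] for c in self.members], dtype=np.intp)


@dataclass(frozen=True)
class ChannelLayout:
    """A named electrode montage (standard 10-20 / 10-10 labels)."""

    name: str
    channels: tuple[str, ...]

    def sensor_set(self) -> SensorSet:
        return SensorSet(self.channels)

    def __len__(self) -> int:
        return len(self.channels)


# 19-channel original 10-20 montage (modern T7/T8/P7/P8 naming).
_LAYOUT_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

# 32-channel commercial actiCAP arrangement.
_LAYOUT_ACTICAP_32 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
)

# 62-channel montage: a standard 64-channel 10-10 set with TP7/TP8 removed.
# This is a reconstruction of such a cap from public label lists, not a copy of
# any particular recording setup.
_LAYOUT_FULL_62 = _LAYOUT_ACTICAP_32 + (
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "CP3", "CPz", "CP4",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
)

BUILTIN_LAYOUTS: dict[str, ChannelLayout] = {
    "1020-19": ChannelLayout("1020-19", _LAYOUT_1020_19),
    "actiCAP-32": ChannelLayout("actiCAP-32", _LAYOUT_ACTICAP_32),
    "full-62": ChannelLayout("full-62", _LAYOUT_FULL_62),
}


def get_layout(name: str) -> ChannelLayout:
    try:
        return BUILTIN_LAYOUTS[name]
    except KeyError:
        raise KeyError(
            f"unknown layout {name!r}; built-ins: {sorted(BUILTIN_LAYOUTS)}"
        ) from None


@dataclass
class ContinuousRun:
    """One continuous multichannel recording with labelled stimulus events.

    ``signal`` is channels x samples; ``events`` is a list of
    ``(onset_sample, stimulus_class)`` with strictly increasing onsets.
    """

    signal: np.ndarray
    sample_rate: float
    channel_names: list[str]
    events: list[tuple[int, str]]
    run_id: str = "run0"
    session_id: str = "session0"
    subject_id: str = "subject0"

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples matrix")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        n = self.signal.shape[1]
        last = -1
        for onset, cls in self.events:
            if not 0 <= onset < n:
                raise ValueError(
                    f"event onset {onset} outside recording [0, {n})"
                )
            if onset <= last:
                raise ValueError("event onsets must be strictly increasing")
            if cls not in STIMULUS_CLASSES:
                raise ValueError(f"unknown stimulus class {cls!r}")
            last = onset

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def restrict(self, sensors: SensorSet) -> "ContinuousRun":
        idx = sensors.indices_in(self.channel_names)
        return replace(
            self,
            signal=self.signal[idx],
            channel_names=[self.channel_names[i] for i in idx],
            events=list(self.events),
        )


@dataclass
class EpochedDataset:
    """Stimulus-locked trials: a trials x channels x samples tensor plus labels."""

    epochs: np.ndarray
    labels: np.ndarray
    window_ms: tuple[float, float]
    sample_rate: float
    channel_names: list[str]
    run_id: str = "run0"
    session_id: str = "session0"
    subject_id: str = "subject0"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if self.epochs.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if self.epochs.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel names")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def class_counts(self) -> dict[str, int]:
        labels = list(self.labels)
        return {c: labels.count(c) for c in STIMULUS_CLASSES}

    def restrict(self, sensors: SensorSet) -> "EpochedDataset":
        idx = sensors.indices_in(self.channel_names)
        return replace(
            self,
            epochs=self.epochs[:, idx, :],
            labels=self.labels.copy(),
            channel_names=[self.channel_names[i] for i in idx],
        )


def restrict(
    data: Union[ContinuousRun, EpochedDataset], sensors: SensorSet
) -> Union[ContinuousRun, EpochedDataset]:
    """Reduce the channel dimension to ``sensors``, in the set's order."""
    return data.restrict(sensors)


def epoch(
    run: ContinuousRun,
    window_ms: tuple[float, float],
) -> EpochedDataset:
    """Cut stimulus-locked windows out of a continuous run.

    The window is half-open ``[start_ms, end_ms)`` relative to each event
    onset.  Events whose window does not fit inside the recording are dropped
    with a logged warning.
    """
    start_ms, end_ms = window_ms
    if end_ms <= start_ms:
        raise ValueError(f"window end {end_ms} must exceed start {start_ms}")
    fs = run.sample_rate
    start_s = int(round(start_ms * fs / 1000.0))
    n_win = int(round((end_ms - start_ms) * fs / 1000.0))
    if n_win < 1:
        raise ValueError("window shorter than one sample")

    trials, labels, dropped = [], [], 0
    for onset, cls in run.events:
        a = onset + start_s
        b = a + n_win
        if a < 0 or b > run.n_samples:
            dropped += 1
            continue
        trials.append(run.signal[:, a:b])
        labels.append(cls)
    if dropped:
        logger.warning(
            "epoch: dropped %d event(s) whose window does not fit in run %s",
            dropped, run.run_id,
        )
    epochs = (
        np.stack(trials)
        if trials
        else np.empty((0, run.n_channels, n_win))
    )
    return EpochedDataset(
        epochs=epochs,
        labels=np.asarray(labels, dtype=object),
        window_ms=(float(start_ms), float(end_ms)),
        sample_rate=fs,
        channel_names=list(run.channel_names),
        run_id=run.run_id,
        session_id=run.session_id,
        subject_id=run.subject_id,
    )


# ---------------------------------------------------------------------------
# dataset bundle I/O


def _signal_filename(run: ContinuousRun) -> str:
    return f"{run.subject_id}_{run.session_id}_{run.run_id}_signal.f32"


def _events_filename(run: ContinuousRun) -> str:
    return f"{run.subject_id}_{run.session_id}_{run.run_id}_events.tsv"


def write_bundle(runs: Sequence[ContinuousRun], path: Union[str, Path]) -> Path:
    """Write runs as a dataset bundle directory; returns the bundle path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for run in runs:
        sig_name = _signal_filename(run)
        ev_name = _events_filename(run)
        run.signal.astype(np.float32).tofile(path / sig_name)
        with open(path / ev_name, "w") as fh:
            fh.write("onset_sample\tstimulus_class\n")
            for onset, cls in run.events:
                fh.write(f"{onset}\t{cls}\n")
        entries.append(
            {
                "run_id": run.run_id,
                "session_id": run.session_id,
                "subject_id": run.subject_id,
                "sample_rate": run.sample_rate,
                "n_channels": run.n_channels,
                "n_samples": run.n_samples,
                "channel_names": list(run.channel_names),
                "signal_file": sig_name,
                "events_file": ev_name,
            }
        )
    meta = {"format": _BUNDLE_FORMAT, "version": 1, "runs": entries}
    with open(path / BUNDLE_METADATA, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


def _require(entry: dict, key: str, context: str):
    if key not in entry:
        raise BundleFormatError(f"{context}: missing field {key!r}")
    return entry[key]


def read_bundle(path: Union[str, Path]) -> list[ContinuousRun]:
    """Read a dataset bundle directory back into :class:`ContinuousRun` objects."""
    path = Path(path)
    meta_path = path / BUNDLE_METADATA
    if not meta_path.exists():
        raise BundleFormatError(f"{path}: missing {BUNDLE_METADATA}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    if meta.get("format") != _BUNDLE_FORMAT:
        raise BundleFormatError(f"{meta_path}: missing/unknown field 'format'")
    runs = []
    for entry in _require(meta, "runs", str(meta_path)):
        ctx = f"{meta_path} run entry"
        n_ch = _require(entry, "n_channels", ctx)
        n_s = _require(entry, "n_samples", ctx)
        names = _require(entry, "channel_names", ctx)
        if len(names) != n_ch:
            raise BundleFormatError(
                f"{ctx}: field 'channel_names' has {len(names)} entries, "
                f"n_channels is {n_ch}"
            )
        sig_file = path / _require(entry, "signal_file", ctx)
        raw = np.fromfile(sig_file, dtype=np.float32)
        if raw.size != n_ch * n_s:
            raise BundleFormatError(
                f"{sig_file}: field 'signal_file' holds {raw.size} values, "
                f"expected {n_ch * n_s}"
            )
        events = []
        ev_file = path / _require(entry, "events_file", ctx)
        with open(ev_file) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["onset_sample", "stimulus_class"]:
                raise BundleFormatError(
                    f"{ev_file}: field 'events_file' has bad header {header}"
                )
            for line in fh:
                if not line.strip():
                    continue
                onset_str, cls = line.rstrip("\n").split("\t")
                events.append((int(onset_str), cls))
        runs.append(
            ContinuousRun(
                signal=raw.reshape(n_ch, n_s).astype(np.float64),
                sample_rate=_require(entry, "sample_rate", ctx),
                channel_names=list(names),
                events=events,
                run_id=_require(entry, "run_id", ctx),
                session_id=_require(entry, "session_id", ctx),
                subject_id=_require(entry, "subject_id", ctx),
            )
        )
    return runs
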