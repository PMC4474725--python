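"""Core domain types for continuous EEG recordings and epoched trials.

A :class:`Recording` holds a multichannel EEG signal (channels x samples, in
microvolts) together with event markers; an :class:`EpochSet` holds cued trial
segments cut around those markers.  Epoching uses 0-based sample indices and
half-open ``[start, end)`` windows so that epoch lengths are unambiguous across
sampling rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "Recording",
    "EpochSet",
    "seconds_to_samples",
    "extract_epochs",
    "center_epochs",
    "read_recording",
    "write_recording",
    "read_markers_csv",
    "write_markers_csv",
]


def seconds_to_samples(t: float, sampling_rate: float) -> int:
    """Convert seconds to a sample count, rounding half away from zero."""
    x = t * sampling_rate
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class Marker:
    """An event marker: cue onset (0-based sample index), class label, duration.

    ``duration_samples`` is 0 for instantaneous cues.
    """

    onset_sample: int
    label: str
    duration_samples: int = 0

    def __post_init__(self) -> None:
        if self.onset_sample < 0:
            raise ValueError(f"marker onset must be >= 0, got {self.onset_sample}")
        if self.duration_samples < 0:
            raise ValueError(
                f"marker duration must be >= 0, got {self.duration_samples}"
            )


@dataclass
class Recording:
    """Continuous multichannel EEG: channels x samples, microvolts."""

    signals: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str]
    markers: list[Marker] = field(default_factory=list)
    recording_id: str | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float64)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples array")
        if self.signals.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        n = self.signals.shape[1]
        for m in self.markers:
            if m.onset_sample >= n or m.onset_sample + m.duration_samples > n:
                raise ValueError(
                    f"marker {m} extends past recording of {n} samples"
                )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class EpochSet:
    """Trials x channels x samples array with one class label per trial.

    ``window`` is the epoch extent in seconds relative to the cue.
    """

    epochs: np.ndarray
    labels: np.ndarray
    sampling_rate: float
    window: tuple[float, float]
    channel_labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per trial required")
        if not self.window[1] > self.window[0]:
            raise ValueError(
                f"epoch window end {self.window[1]} must exceed start {self.window[0]}"
            )

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Distinct labels in sorted order (the canonical class order)."""
        return np.unique(self.labels)


def extract_epochs(
    recording: Recording,
    window_start_s: float,
    window_end_s: float,
    label_map: Mapping[str, str] | None = None,
) -> EpochSet:
    """Cut one epoch per retained marker from a continuous recording.

    The epoch for a marker at sample ``o`` covers samples
    ``[o + round(start*fs), o + round(end*fs))`` (half-open).  Markers whose
    label is missing from ``label_map`` are dropped; ``label_map=None`` keeps
    every marker under its own label.
    """
    if not window_end_s > window_start_s:
        raise ValueError(
            f"window end {window_end_s}s must exceed start {window_start_s}s"
        )
    fs = recording.sampling_rate
    off_start = seconds_to_samples(window_start_s, fs)
    off_end = seconds_to_samples(window_end_s, fs)
    length = off_end - off_start
    if length < 1:
        raise ValueError("window shorter than one sample")

    segments, labels = [], []
    for m in recording.markers:
        if label_map is not None:
            if m.label not in label_map:
                continue
            label = label_map[m.label]
        else:
            label = m.label
        a = m.onset_sample + off_start
        b = a + length
        if a < 0 or b > recording.n_samples:
            raise ValueError(
                f"epoch window [{a}, {b}) for marker {m} is outside the "
                f"recording of {recording.n_samples} samples"
            )
        segments.append(recording.signals[:, a:b])
        labels.append(label)
    return EpochSet(
        epochs=np.stack(segments) if segments else np.empty((0, recording.n_channels, length)),
        labels=np.asarray(labels, dtype=object),
        sampling_rate=fs,
        window=(window_start_s, window_end_s),
        channel_labels=list(recording.channel_labels),
    )


def center_epochs(epochs: EpochSet) -> EpochSet:
    """Remove the per-trial per-channel mean from every time series.

    This is the standardisation step applied before CSP: with the mean gone,
    the variance of a band-pass-filtered channel equals its band power.  No
    variance scaling is applied.
    """
    centered = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    return replace(epochs, epochs=centered)


# ---------------------------------------------------------------------------
# Container I/O: HDF5 for recordings, CSV for marker tables.

_MARKER_DTYPE = np.dtype(
    [("onset_sample", np.int64), ("label", h5py.string_dtype()), ("duration_samples", np.int64)]
)


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to the HDF5 container layout.

    Datasets: ``/signals`` (channels x samples float64), ``/markers`` (table of
    onset_sample, label, duration_samples); attributes ``sampling_rate`` and
    ``channel_labels``.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=recording.signals)
        table = np.array(
            [(m.onset_sample, m.label, m.duration_samples) for m in recording.markers],
            dtype=_MARKER_DTYPE,
        )
        f.create_dataset("markers", data=table)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.attrs["channel_labels"] = [str(c) for c in recording.channel_labels]
        if recording.recording_id is not None:
            f.attrs["recording_id"] = recording.recording_id


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording` (bit-exact)."""
    with h5py.File(path, "r") as f:
        signals = f["signals"][()]
        raw = f["markers"][()]
        markers = [
            Marker(
                int(r["onset_sample"]),
                r["label"].decode() if isinstance(r["label"], bytes) else str(r["label"]),
                int(r["duration_samples"]),
            )
            for r in raw
        ]
        rec_id = f.attrs.get("recording_id")
        return Recording(
            signals=signals,
            sampling_rate=float(f.attrs["sampling_rate"]),
            channel_labels=[str(c) for c in f.attrs["channel_labels"]],
            markers=markers,
            recording_id=None if rec_id is None else str(rec_id),
        )


def write_markers_csv(markers: Sequence[Marker], path: str | Path) -> None:
    pd.DataFrame(
        [(m.onset_sample, m.label, m.duration_samples) for m in markers],
        columns=["onset_sample", "label", "duration_samples"],
    ).to_csv(path, index=False)


def read_markers_csv(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path)
    return [
        Marker(int(r.onset_sample), str(r.label), int(r.duration_samples))
        for r in df.itertuples()
    ]
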