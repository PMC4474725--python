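"""Band-power feature extraction.

Two families are provided.  The direct band-power (BP) family measures the
time-averaged squared amplitude of each (band-pass filtered, usually
CSP-projected) channel, plus its natural logarithm.  The Morlet family
convolves each channel with complex Morlet wavelets on a lattice of centre
frequencies and averages the squared magnitude over time, giving a narrow-band
power estimate per centre frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import EpochSet

__all__ = [
    "FeatureMatrix",
    "MorletSpec",
    "band_power",
    "bp_features",
    "morlet_features",
]

#: Floor applied inside log(band power) so filtered all-zero segments stay finite.
LOG_FLOOR = 1e-12


@dataclass
class FeatureMatrix:
    """Samples x features with per-column provenance names and per-row labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.labels):
            raise ValueError("one label per row required")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("one name per column required")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if not np.array_equal(self.labels, other.labels):
            raise ValueError("cannot stack feature matrices with different labels")
        return FeatureMatrix(
            values=np.hstack([self.values, other.values]),
            feature_names=self.feature_names + other.feature_names,
            labels=self.labels,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)


def _default_centers() -> tuple[float, ...]:
    # 1-Hz bands tiling 4-30 Hz -> 26 centre frequencies
    return tuple(np.arange(4.5, 30.0, 1.0))


@dataclass(frozen=True)
class MorletSpec:
    """Morlet decomposition: centre frequencies (Hz) and wavelet width in cycles.

    The default lattice is 26 centre frequencies at 1-Hz spacing from 4.5 to
    29.5 Hz (1-Hz bands tiling 4-30 Hz), 7 cycles wide.
    """

    center_frequencies: tuple[float, ...] = field(default_factory=_default_centers)
    cycles: float = 7.0

    def __post_init__(self) -> None:
        f = np.asarray(self.center_frequencies)
        if len(f) == 0 or not np.all(np.diff(f) > 0) or f[0] <= 0:
            raise ValueError("center frequencies must be strictly increasing and positive")
        if not self.cycles > 0:
            raise ValueError("cycles must be positive")


def band_power(segment: np.ndarray) -> float:
    """Time-averaged power of a single-channel segment: mean of squared samples.

    Time-averaging (rather than a raw sum of squares) keeps features comparable
    across candidate time segments of different lengths.
    """
    segment = np.asarray(segment)
    if segment.size == 0:
        raise ValueError("cannot compute band power of an empty segment")
    return float(np.mean(np.square(segment)))


def bp_features(
    per_band_epochs: Sequence[EpochSet],
    band_names: Sequence[str] | None = None,
    include_log: bool = True,
) -> FeatureMatrix:
    """Direct band-power features: power and log(power) per band per channel.

    ``per_band_epochs`` is the output of the filter bank (possibly after CSP
    projection, in which case channels are surrogate channels).  Feature count
    is ``2 x bands x channels`` with the log variant, ``bands x channels``
    without.
    """
    if len(per_band_epochs) == 0:
        raise ValueError("no bands given")
    first = per_band_epochs[0]
    for es in per_band_epochs[1:]:
        if es.n_trials != first.n_trials or not np.array_equal(es.labels, first.labels):
            raise ValueError("per-band epoch sets have inconsistent trials/labels")
    if band_names is None:
        band_names = [f"band{i}" for i in range(len(per_band_epochs))]

    cols, names = [], []
    for bname, es in zip(band_names, per_band_epochs):
        power = np.mean(np.square(es.epochs), axis=2)  # trials x channels
        chans = (
            list(es.channel_labels)
            if es.channel_labels is not None
            else [f"ch{j}" for j in range(es.n_channels)]
        )
        for j, ch in enumerate(chans):
            cols.append(power[:, j])
            names.append(f"{bname}/{ch}/pow")
            if include_log:
                cols.append(np.log(np.maximum(power[:, j], LOG_FLOOR)))
                names.append(f"{bname}/{ch}/logpow")
    return FeatureMatrix(
        values=np.column_stack(cols), feature_names=names, labels=first.labels
    )


def _morlet_wavelet(freq: float, cycles: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, unit energy (sum |w|^2 = 1), support +-3 sigma."""
    sigma_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(3.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2.0 * sigma_t**2)) * np.exp(2j * np.pi * freq * t)
    return w / np.linalg.norm(w)


def morlet_features(epochs: EpochSet, spec: MorletSpec | None = None,
                    include_log: bool = False) -> FeatureMatrix:
    """Morlet band-power features: one column per channel per centre frequency.

    Each channel is convolved ('same' length) with a unit-energy complex Morlet
    wavelet and the squared magnitude is averaged over time.  With the default
    spec this yields 26 features per channel.
    """
    spec = spec or MorletSpec()
    fs = epochs.sampling_rate
    nyq = fs / 2.0
    if spec.center_frequencies[-1] >= nyq:
        raise ValueError("centre frequency at or above Nyquist")
    lowest = spec.center_frequencies[0]
    support = len(_morlet_wavelet(lowest, spec.cycles, fs))
    if support > epochs.n_samples:
        raise ValueError(
            f"wavelet at {lowest} Hz spans {support} samples but epochs have "
            f"only {epochs.n_samples}"
        )
    chans = (
        list(epochs.channel_labels)
        if epochs.channel_labels is not None
        else [f"ch{j}" for j in range(epochs.n_channels)]
    )
    cols, names = [], []
    flat = epochs.epochs.reshape(-1, epochs.n_samples)
    for f in spec.center_frequencies:
        w = _morlet_wavelet(f, spec.cycles, fs)
        conv = sps.fftconvolve(flat, w[None, :], mode="same", axes=1)
        power = np.mean(np.abs(conv) ** 2, axis=1).reshape(epochs.n_trials, epochs.n_channels)
        for j, ch in enumerate(chans):
            cols.append(power[:, j])
            names.append(f"morlet{f:g}Hz/{ch}/pow")
            if include_log:
                cols.append(np.log(np.maximum(power[:, j], LOG_FLOOR)))
                names.append(f"morlet{f:g}Hz/{ch}/logpow")
    return FeatureMatrix(
        values=np.column_stack(cols), feature_names=names, labels=epochs.labels
    )
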