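"""Butterworth filter banks.

A filter bank is an ordered array of band-pass blocks; applying it to a
recording or epoch set yields one filtered copy per band.  Filters are
fifth-order Butterworth by default (maximally flat pass band) and are applied
forward-backward, so the output is zero-phase and the effective magnitude
response is the squared single-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .core import EpochSet, Recording

__all__ = ["BandSpec", "FilterBank", "design_bandpass", "apply_filterbank"]

DEFAULT_ORDER = 5

#: Default bands for the direct band-power pipeline: mu/alpha and beta.
ALPHA_BETA_BANK_BANDS = [(8.0, 12.0), (16.0, 24.0)]
#: Broad pre-filter used ahead of Morlet decomposition.
BROADBAND = (4.0, 30.0)


@dataclass(frozen=True)
class BandSpec:
    """One pass band in Hz; must satisfy 0 < low < high < Nyquist when applied."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got ({self.low_hz}, {self.high_hz})"
            )


@dataclass(frozen=True)
class FilterBank:
    bands: tuple[BandSpec, ...]
    order: int = DEFAULT_ORDER

    def __post_init__(self) -> None:
        if len(self.bands) < 1:
            raise ValueError("filter bank needs at least one band")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    @classmethod
    def from_pairs(cls, pairs, order: int = DEFAULT_ORDER) -> "FilterBank":
        return cls(tuple(BandSpec(float(lo), float(hi)) for lo, hi in pairs), order)


def design_bandpass(band: BandSpec, sampling_rate: float, order: int = DEFAULT_ORDER):
    """Design a Butterworth band-pass; returns ``(b, a)`` transfer coefficients."""
    nyq = sampling_rate / 2.0
    if band.high_hz >= nyq:
        raise ValueError(
            f"band edge {band.high_hz} Hz reaches the Nyquist frequency {nyq} Hz"
        )
    return sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass", fs=sampling_rate)


def _filtfilt(x: np.ndarray, b: np.ndarray, a: np.ndarray) -> np.ndarray:
    # scipy's default padlen is 3*max(len(a), len(b)) = 3*(2*order + 1) for a
    # band-pass; truncate for epochs too short for the full odd extension.
    padlen = min(3 * max(len(a), len(b)), x.shape[-1] - 1)
    return sps.filtfilt(b, a, x, axis=-1, padlen=padlen)


def apply_filterbank(data: EpochSet | Recording, bank: FilterBank) -> list:
    """Filter through every band of the bank; one same-shaped copy per band."""
    if isinstance(data, EpochSet):
        n = data.n_samples
        fs = data.sampling_rate
    elif isinstance(data, Recording):
        n = data.n_samples
        fs = data.sampling_rate
    else:
        raise TypeError(f"cannot filter {type(data).__name__}")
    if n < 3 * bank.order + 1:
        raise ValueError(
            f"signal of {n} samples is shorter than the filter warm-up "
            f"({3 * bank.order + 1} samples at order {bank.order})"
        )
    out = []
    for band in bank.bands:
        b, a = design_bandpass(band, fs, bank.order)
        if isinstance(data, EpochSet):
            out.append(replace(data, epochs=_filtfilt(data.epochs, b, a)))
        else:
            out.append(
                Recording(
                    signals=_filtfilt(data.signals, b, a),
                    sampling_rate=fs,
                    channel_labels=list(data.channel_labels),
                    markers=list(data.markers),
                    recording_id=data.recording_id,
                )
            )
    return out
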