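"""Synthetic sensory-motor EEG with controllable ERD/ERS.

The generator emulates the class-dependent power modulation that motor imagery
produces in real EEG: a small number of band-limited oscillatory sources
(alpha ~8-12 Hz, beta ~16-24 Hz) are mixed linearly into channels, and each
class attenuates (ERD, factor < 1) or enhances (ERS, factor > 1) the *power*
of selected sources.  Sources are band-pass-filtered Gaussian noise, not pure
tones, so CSP faces realistic broadband-in-band variance.  White Gaussian
sensor noise is added on top.

Two layouts are produced: cued trials in randomised class order (synchronous
operation) and a continuous stream of alternating control / No-Control
stretches (self-paced operation).

Randomness is split from one global integer seed into per-segment streams via
``numpy`` seed sequences keyed by ``(purpose_tag, segment_index, source)``, so
changing the trial count never reshuffles earlier trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import Marker, Recording, seconds_to_samples
from .filterbank import BandSpec, design_bandpass, _filtfilt

__all__ = [
    "SynthConfig",
    "SelfPacedConfig",
    "generate_synchronous",
    "generate_selfpaced",
    "write_intervals_csv",
    "read_intervals_csv",
]

_SOURCE_FILTER_ORDER = 4

# stream tags for the seed-splitting scheme
_TAG_CLASS_ORDER = 0
_TAG_MIXING = 1
_TAG_TRIAL_SOURCE = 2
_TAG_TRIAL_NOISE = 3
_TAG_INTERVALS = 4


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class SynthConfig:
    """Study conditions for the cued-trial (synchronous) generator.

    ``modulation`` maps class label -> one multiplicative power factor per
    source (1 = no change, < 1 = ERD, > 1 = ERS); amplitudes are scaled by the
    square root of the factor since ERD/ERS is defined on power.  ``mixing``
    (channels x sources) defaults to a seed-derived random full-rank matrix.
    """

    n_channels: int = 8
    sampling_rate: float = 250.0
    classes: tuple[str, ...] = ("left", "right")
    trials_per_class: int = 100
    trial_length_s: float = 4.0
    inter_trial_s: float = 1.0
    source_bands: tuple[tuple[float, float, float], ...] = (
        (8.0, 12.0, 1.0),
        (16.0, 24.0, 1.0),
    )
    modulation: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"left": (1.0, 1.0), "right": (0.3, 1.0)}
    )
    mixing: np.ndarray | None = None
    noise_sd: float = 0.5
    seed: int = 0
    session: int = 0

    def __post_init__(self) -> None:
        n_src = len(self.source_bands)
        for c in self.classes:
            if c not in self.modulation:
                raise ValueError(f"no modulation row for class {c!r}")
            row = np.asarray(self.modulation[c], dtype=float)
            if len(row) != n_src:
                raise ValueError(
                    f"modulation row for {c!r} has {len(row)} factors, "
                    f"expected {n_src}"
                )
            if np.any(row < 0):
                raise ValueError("modulation factors must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mixing is None:
            self.mixing = _rng(self.seed, _TAG_MIXING).normal(
                size=(self.n_channels, n_src)
            ) / np.sqrt(n_src)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.mixing.shape != (self.n_channels, n_src):
            raise ValueError(
                f"mixing must be {self.n_channels} x {n_src}, got {self.mixing.shape}"
            )
        if np.linalg.matrix_rank(self.mixing) < n_src:
            raise ValueError("mixing matrix is rank-deficient")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        if "classes" in d:
            d["classes"] = tuple(d["classes"])
        if "source_bands" in d:
            d["source_bands"] = tuple(tuple(b) for b in d["source_bands"])
        if "mixing" in d and d["mixing"] is not None:
            d["mixing"] = np.asarray(d["mixing"], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


@dataclass
class SelfPacedConfig(SynthConfig):
    """Conditions for the continuous self-paced generator.

    Control and No-Control stretch lengths are drawn uniformly from
    ``control_interval_range_s`` (matching evaluation sessions where imagery
    intervals vary between 1.5 and 8 s); ERD/ERS modulation applies only inside
    control stretches, using the modulation row of ``classes[0]``.
    """

    control_interval_range_s: tuple[float, float] = (1.5, 8.0)
    total_length_s: float = 120.0

    def __post_init__(self) -> None:
        super().__post_init__()
        lo, hi = self.control_interval_range_s
        if not 0 < lo <= hi:
            raise ValueError("control interval range must satisfy 0 < min <= max")
        if not self.total_length_s > hi:
            raise ValueError("total_length_s must exceed the maximum interval length")


def _bandlimited_noise(
    n: int, band: BandSpec, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band``."""
    b, a = design_bandpass(band, fs, _SOURCE_FILTER_ORDER)
    x = _filtfilt(rng.standard_normal(n)[None, :], b, a)[0]
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _render_segment(
    cfg: SynthConfig, n: int, factors: np.ndarray, seg_index: int
) -> np.ndarray:
    """Mix modulated sources plus sensor noise for one contiguous segment."""
    sources = np.empty((len(cfg.source_bands), n))
    for s, (lo, hi, amp) in enumerate(cfg.source_bands):
        rng = _rng(cfg.seed, _TAG_TRIAL_SOURCE, cfg.session, seg_index, s)
        sources[s] = _bandlimited_noise(n, BandSpec(lo, hi), cfg.sampling_rate, rng)
        sources[s] *= amp * np.sqrt(factors[s])
    x = cfg.mixing @ sources
    if cfg.noise_sd > 0:
        x = x + cfg.noise_sd * _rng(cfg.seed, _TAG_TRIAL_NOISE, cfg.session, seg_index).standard_normal(
            x.shape
        )
    return x


def generate_synchronous(config: SynthConfig) -> Recording:
    """Generate a cued-trial recording with one marker per trial.

    Trials of all classes are interleaved in a seed-determined random order,
    separated by unmodulated inter-trial baseline; identical seeds give
    bit-identical output.
    """
    fs = config.sampling_rate
    n_trial = seconds_to_samples(config.trial_length_s, fs)
    n_gap = seconds_to_samples(config.inter_trial_s, fs)
    # class order is randomised block-by-block (one trial of each class per
    # block, shuffled with a per-block stream): classes stay exactly balanced
    # and raising trials_per_class never reshuffles earlier trials
    order = []
    for block in range(config.trials_per_class):
        chunk = np.asarray(config.classes, dtype=object)
        _rng(config.seed, _TAG_CLASS_ORDER, config.session, block).shuffle(chunk)
        order.extend(chunk)

    ones = np.ones(len(config.source_bands))
    chunks, markers = [], []
    pos = 0
    seg = 0
    for label in order:
        if n_gap > 0:
            chunks.append(_render_segment(config, n_gap, ones, seg))
            seg += 1
            pos += n_gap
        factors = np.asarray(config.modulation[label], dtype=float)
        chunks.append(_render_segment(config, n_trial, factors, seg))
        markers.append(Marker(pos, str(label), n_trial))
        seg += 1
        pos += n_trial
    if n_gap > 0:
        chunks.append(_render_segment(config, n_gap, ones, seg))

    return Recording(
        signals=np.concatenate(chunks, axis=1),
        sampling_rate=fs,
        channel_labels=[f"ch{i}" for i in range(config.n_channels)],
        markers=markers,
    )


def generate_selfpaced(
    config: SelfPacedConfig,
) -> tuple[Recording, list[tuple[int, int]]]:
    """Generate a continuous stream of alternating No-Control/control stretches.

    Returns the recording and the half-open, sorted, non-overlapping control
    intervals ``(start_sample, end_sample)``.  Stretch lengths are uniform on
    the configured range; the stream starts with a No-Control stretch; the
    final stretch is truncated to make the sample accounting exact, and if a
    truncated *control* stretch falls below the minimum length it is emitted
    as No-Control instead so every reported control interval respects the
    range.  Control onsets also appear as markers (label = first class).
    """
    fs = config.sampling_rate
    total = seconds_to_samples(config.total_length_s, fs)
    lo, hi = config.control_interval_range_s
    min_n = seconds_to_samples(lo, fs)
    rng = _rng(config.seed, _TAG_INTERVALS, config.session)

    control_label = config.classes[0]
    mod_row = np.asarray(config.modulation[control_label], dtype=float)
    ones = np.ones_like(mod_row)

    segments = []  # (n_samples, is_control)
    pos = 0
    is_control = False  # start with a No-Control stretch
    while pos < total:
        n = seconds_to_samples(float(rng.uniform(lo, hi)), fs)
        if pos + n > total:
            n = total - pos
            if is_control and n < min_n:
                is_control = False
        segments.append((n, is_control))
        pos += n
        is_control = not is_control

    chunks, intervals, markers = [], [], []
    pos = 0
    for seg_index, (n, ctrl) in enumerate(segments):
        factors = mod_row if ctrl else ones
        chunks.append(_render_segment(config, n, factors, seg_index))
        if ctrl:
            intervals.append((pos, pos + n))
            markers.append(Marker(pos, str(control_label), n))
        pos += n

    rec = Recording(
        signals=np.concatenate(chunks, axis=1),
        sampling_rate=fs,
        channel_labels=[f"ch{i}" for i in range(config.n_channels)],
        markers=markers,
    )
    return rec, intervals


def write_intervals_csv(intervals, path) -> None:
    pd.DataFrame(intervals, columns=["start_sample", "end_sample"]).to_csv(
        path, index=False
    )


def read_intervals_csv(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [(int(r.start_sample), int(r.end_sample)) for r in df.itertuples()]
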