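"""Performance scoring for synchronous and self-paced operation.

Synchronous (cued) operation is scored by per-trial classification accuracy.
Self-paced operation is a sequential detection problem: the continuous stream
is cut into overlapping sliding windows, each window is scored with the
classifier's control-class probability, and the score/label pairs are
summarised by the ROC curve and its area (AUC).  AUC equals the probability
that a random control window outscores a random No-Control window, with half
credit for ties (the normalised Mann-Whitney U statistic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .core import EpochSet, Recording, seconds_to_samples

__all__ = [
    "SlidingWindowConfig",
    "ScoredWindows",
    "accuracy",
    "make_windows",
    "roc_curve",
    "auc",
    "CONTROL_LABEL",
    "NC_LABEL",
]

CONTROL_LABEL = "control"
NC_LABEL = "nc"


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Sliding-window geometry: window length (s) and fractional overlap [0, 1)."""

    window_length_s: float = 2.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.window_length_s > 0:
            raise ValueError("window length must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap fraction must lie in [0, 1)")

    def step_samples(self, sampling_rate: float) -> int:
        step = seconds_to_samples(
            self.window_length_s * (1 - self.overlap_fraction), sampling_rate
        )
        if step < 1:
            raise ValueError("window step is below one sample")
        return step


@dataclass
class ScoredWindows:
    """Per-window control-class scores with binary ground truth."""

    scores: np.ndarray
    labels: np.ndarray  # True = control, False = No-Control
    window_starts: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if not (len(self.scores) == len(self.labels) == len(self.window_starts)):
            raise ValueError("scores, labels and window_starts must align")
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("scores must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "window_start": self.window_starts,
                "score": self.scores,
                "label": np.where(self.labels, CONTROL_LABEL, NC_LABEL),
            }
        ).to_csv(path, index=False)


def accuracy(predicted: Sequence, truth: Sequence) -> float:
    """Fraction of exactly matching labels."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) == 0:
        raise ValueError("cannot score empty label vectors")
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(truth)} truths"
        )
    return float(np.mean(predicted == truth))


def make_windows(
    recording: Recording,
    control_intervals: Sequence[tuple[int, int]],
    config: SlidingWindowConfig,
) -> tuple[EpochSet, np.ndarray]:
    """Cut half-open sliding windows and label each control / No-Control.

    A window is labelled control when at least half of its samples fall inside
    some control interval (majority rule; the tie at exactly 50 % counts as
    control).  Returns the windows as an :class:`EpochSet` with labels
    ``control``/``nc`` and the array of window start samples.
    """
    fs = recording.sampling_rate
    n_win = seconds_to_samples(config.window_length_s, fs)
    if n_win > recording.n_samples:
        raise ValueError(
            f"window of {n_win} samples exceeds recording of {recording.n_samples}"
        )
    step = config.step_samples(fs)

    inside = np.zeros(recording.n_samples, dtype=bool)
    for a, b in control_intervals:
        inside[a:b] = True
    cum = np.concatenate([[0], np.cumsum(inside)])

    starts = np.arange(0, recording.n_samples - n_win + 1, step)
    segs = np.stack([recording.signals[:, s : s + n_win] for s in starts])
    covered = cum[starts + n_win] - cum[starts]
    labels = np.where(covered * 2 >= n_win, CONTROL_LABEL, NC_LABEL)
    windows = EpochSet(
        epochs=segs,
        labels=labels.astype(object),
        sampling_rate=fs,
        window=(0.0, config.window_length_s),
        channel_labels=list(recording.channel_labels),
    )
    return windows, starts


def roc_curve(scored: ScoredWindows) -> np.ndarray:
    """ROC staircase as an array of (FPR, TPR) points from (0,0) to (1,1)."""
    y = scored.labels
    if y.all() or not y.any():
        raise ValueError("ROC needs both control and No-Control windows")
    fpr, tpr, _ = _skm.roc_curve(y, scored.scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(scored: ScoredWindows) -> float:
    """Trapezoidal area under the ROC curve.

    Numerically identical to the normalised Mann-Whitney U statistic with half
    credit for tied scores.
    """
    pts = roc_curve(scored)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_points_to_csv(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, index=False)
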