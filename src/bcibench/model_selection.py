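"""Joint model selection over BCI parameters and classifier hyperparameters.

The tunable "BCI parameters" are the epoch time segment and the number of CSP
filter pairs for cued (synchronous) data, and the sliding-window geometry for
self-paced data.  These are searched jointly with each classifier's own grid
by exhaustive enumeration, scoring every candidate with repeated stratified
k-fold cross-validation (5 x 5-fold by default; accuracy for synchronous,
AUC for self-paced).  Supervised steps (CSP, feature standardisation, the
classifier) are refit inside each training fold so no test-fold labels leak
into the fit.  The winning configuration is refit on the full training data
and scored once on an independent test set.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import csp as _csp
from .classifiers import ClassifierSpec, ParamGrid, predict_proba, train
from .core import EpochSet, Recording, center_epochs, extract_epochs
from .evaluation import (
    CONTROL_LABEL,
    ScoredWindows,
    SlidingWindowConfig,
    accuracy,
    auc,
    make_windows,
)
from .features import FeatureMatrix, MorletSpec, bp_features, morlet_features
from .filterbank import ALPHA_BETA_BANK_BANDS, BROADBAND, FilterBank, apply_filterbank

__all__ = [
    "PipelineConfig",
    "SearchSpace",
    "CVResult",
    "crossval_score",
    "grid_search",
    "fit_final_and_test",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One fully specified pipeline: filtering, CSP, features, classifier.

    ``time_segment`` applies to synchronous data, ``window`` to self-paced
    data; ``n_csp_pairs=None`` skips spatial filtering and feeds raw channels
    to feature extraction.
    """

    classifier: ClassifierSpec
    feature_family: str = "bp"  # "bp" | "morlet"
    bands: tuple[tuple[float, float], ...] | None = None
    n_csp_pairs: int | None = 1
    time_segment: tuple[float, float] | None = (0.5, 2.5)
    window: SlidingWindowConfig | None = None
    morlet: MorletSpec | None = None
    morlet_log: bool = False

    def __post_init__(self) -> None:
        if self.feature_family not in ("bp", "morlet"):
            raise ValueError(f"unknown feature family {self.feature_family!r}")

    def effective_bands(self) -> tuple[tuple[float, float], ...]:
        if self.bands is not None:
            return self.bands
        if self.feature_family == "bp":
            return tuple(ALPHA_BETA_BANK_BANDS)
        return (BROADBAND,)

    def describe(self) -> str:
        return json.dumps(
            {
                "classifier": self.classifier.kind,
                "params": dict(sorted(self.classifier.hyperparameters.items())),
                "features": self.feature_family,
                "bands": self.effective_bands(),
                "csp_pairs": self.n_csp_pairs,
                "segment": self.time_segment,
                "window": None
                if self.window is None
                else [self.window.window_length_s, self.window.overlap_fraction],
            },
            default=str,
        )


@dataclass
class SearchSpace:
    """Candidate axes for the joint grid search."""

    classifier_grids: Mapping[str, ParamGrid]
    feature_family: str = "bp"
    time_segments: Sequence[tuple[float, float]] = ((0.5, 2.5),)
    csp_pairs: Sequence[int | None] = (1, 2, 3)
    window_configs: Sequence[SlidingWindowConfig] = (SlidingWindowConfig(2.0, 0.5),)

    def __post_init__(self) -> None:
        if len(self.classifier_grids) == 0:
            raise ValueError("search space has no classifier grids")
        for axis, vals in (
            ("time_segments", self.time_segments),
            ("csp_pairs", self.csp_pairs),
            ("window_configs", self.window_configs),
        ):
            if len(vals) == 0:
                raise ValueError(f"search-space axis {axis} is empty")


@dataclass
class CVResult:
    mean_score: float
    fold_scores: np.ndarray  # repeats x folds
    config: PipelineConfig
    seed: int
    n_repeats: int
    n_folds: int


# ---------------------------------------------------------------------------
# Pipeline internals: band filtering (unsupervised, per-trial) happens once;
# CSP and the classifier are refit per fold on training trials only.


def _banded(epochs: EpochSet, config: PipelineConfig) -> list[tuple[str, EpochSet]]:
    bank = FilterBank.from_pairs(config.effective_bands())
    filtered = apply_filterbank(center_epochs(epochs), bank)
    return [
        (f"{b.low_hz:g}-{b.high_hz:g}Hz", es) for b, es in zip(bank.bands, filtered)
    ]


def _subset(es: EpochSet, idx: np.ndarray) -> EpochSet:
    return replace(es, epochs=es.epochs[idx], labels=es.labels[idx])


def _fit_spatial(banded_train, config: PipelineConfig):
    """Per band: a list of selected CSP filter sets (one for 2-class, one per
    class for multiclass one-against-others), or None when CSP is disabled."""
    if config.n_csp_pairs is None:
        return [None] * len(banded_train)
    state = []
    for _name, es in banded_train:
        classes = es.classes
        if len(classes) == 2:
            pair = _csp.CovariancePair(
                sigma_pos=_csp.class_covariance(es, classes[0]),
                sigma_neg=_csp.class_covariance(es, classes[1]),
            )
            sets = [_csp.fit_csp(pair, class_pair=(str(classes[0]), str(classes[1])))]
        else:
            sets = _csp.fit_csp_ovr(es)
        state.append([_csp.select_filters(s, config.n_csp_pairs) for s in sets])
    return state


def _featurize(banded, spatial_state, config: PipelineConfig) -> FeatureMatrix:
    blocks: list[tuple[str, EpochSet]] = []
    for (name, es), sets in zip(banded, spatial_state):
        if sets is None:
            blocks.append((name, es))
        else:
            for s in sets:
                proj = _csp.apply_csp(s, es)
                tag = name if len(sets) == 1 else f"{name}/ovr-{s.class_pair[0]}"
                blocks.append((tag, proj))
    if config.feature_family == "bp":
        return bp_features([es for _, es in blocks], band_names=[n for n, _ in blocks])
    mats = []
    for name, es in blocks:
        m = morlet_features(es, spec=config.morlet, include_log=config.morlet_log)
        m.feature_names = [f"{name}/{fn}" for fn in m.feature_names]
        mats.append(m)
    out = mats[0]
    for m in mats[1:]:
        out = out.hstack(m)
    return out


def _fit_on(banded_train, config: PipelineConfig):
    spatial = _fit_spatial(banded_train, config)
    feats = _featurize(banded_train, spatial, config)
    model = train(config.classifier, feats)
    return spatial, model


def _score_sync(banded_test, spatial, model, config) -> tuple[float, np.ndarray]:
    feats = _featurize(banded_test, spatial, config)
    pred = predict_proba(model, feats).predicted_labels()
    return accuracy(pred, feats.labels), pred


def _score_selfpaced(banded_test, spatial, model, config, starts) -> tuple[float, ScoredWindows]:
    feats = _featurize(banded_test, spatial, config)
    res = predict_proba(model, feats)
    ctrl_col = int(np.flatnonzero(res.class_order == CONTROL_LABEL)[0])
    scored = ScoredWindows(
        scores=res.probabilities[:, ctrl_col],
        labels=feats.labels == CONTROL_LABEL,
        window_starts=starts,
    )
    return auc(scored), scored


def _fold_seed(seed: int, repeat: int) -> int:
    return int(np.random.SeedSequence((seed, repeat)).generate_state(1)[0] % (2**31))


def _sync_epochs(recording: Recording, label_map, config: PipelineConfig) -> EpochSet:
    if config.time_segment is None:
        raise ValueError("synchronous pipeline needs a time segment")
    return extract_epochs(recording, *config.time_segment, label_map=label_map)


def _selfpaced_windows(recording: Recording, intervals, config: PipelineConfig):
    if config.window is None:
        raise ValueError("self-paced pipeline needs a sliding-window config")
    return make_windows(recording, intervals, config.window)


def crossval_score(
    config: PipelineConfig,
    recording: Recording,
    label_map: Mapping[str, str] | None = None,
    control_intervals: Sequence[tuple[int, int]] | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold score of one pipeline configuration.

    Synchronous mode (``control_intervals is None``) folds over cued trials and
    scores accuracy; self-paced mode folds over sliding windows and scores AUC.
    Deterministic given ``seed``.
    """
    selfpaced = control_intervals is not None
    if selfpaced:
        windows, starts = _selfpaced_windows(recording, control_intervals, config)
        data = windows
    else:
        data = _sync_epochs(recording, label_map, config)
        starts = None

    labels = data.labels.astype(str)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples; need >= {n_folds} for "
            f"{n_folds}-fold CV"
        )
    banded = _banded(data, config)

    scores = np.empty((n_repeats, n_folds))
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=_fold_seed(seed, r))
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            banded_tr = [(n, _subset(es, tr)) for n, es in banded]
            banded_te = [(n, _subset(es, te)) for n, es in banded]
            spatial, model = _fit_on(banded_tr, config)
            if selfpaced:
                s, _ = _score_selfpaced(banded_te, spatial, model, config, starts[te])
            else:
                s, _ = _score_sync(banded_te, spatial, model, config)
            scores[r, f] = s
    return CVResult(
        mean_score=float(scores.mean()),
        fold_scores=scores,
        config=config,
        seed=seed,
        n_repeats=n_repeats,
        n_folds=n_folds,
    )


def _enumerate_configs(space: SearchSpace, selfpaced: bool, seed: int):
    """Yield (tie_break_key, config); enumeration order fixes tie-breaking:
    earlier time segment / window, then fewer CSP pairs, then classifier kind
    and lexicographically smaller parameters."""
    outer = (
        list(enumerate(space.window_configs))
        if selfpaced
        else list(enumerate(space.time_segments))
    )
    pair_axis = sorted(space.csp_pairs, key=lambda p: (p is None, p))
    for (oi, outer_val), (pi, pairs) in itertools.product(outer, enumerate(pair_axis)):
        for kind in space.classifier_grids:
            grid = space.classifier_grids[kind]
            for params in grid.configurations():
                key = (oi, pi, kind, json.dumps(params, sort_keys=True, default=str))
                cfg = PipelineConfig(
                    classifier=ClassifierSpec(kind=kind, hyperparameters=params, seed=seed),
                    feature_family=space.feature_family,
                    n_csp_pairs=pairs,
                    time_segment=None if selfpaced else outer_val,
                    window=outer_val if selfpaced else None,
                )
                yield key, cfg


def grid_search(
    space: SearchSpace,
    recording: Recording,
    label_map: Mapping[str, str] | None = None,
    control_intervals: Sequence[tuple[int, int]] | None = None,
    n_repeats: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    trace: list | None = None,
) -> tuple[PipelineConfig, CVResult]:
    """Exhaustive Cartesian search; returns the best configuration and its CV result.

    Ties on mean score break deterministically toward the earlier time
    segment (or window config), fewer CSP pairs, then lexicographically
    smaller classifier parameters.  ``trace`` (optional list) collects one
    ``(config_id, repeat, fold, score)`` row per fold evaluation.
    """
    selfpaced = control_intervals is not None
    best: tuple | None = None
    for key, cfg in _enumerate_configs(space, selfpaced, seed):
        result = crossval_score(
            cfg,
            recording,
            label_map=label_map,
            control_intervals=control_intervals,
            n_repeats=n_repeats,
            n_folds=n_folds,
            seed=seed,
        )
        if trace is not None:
            cid = cfg.describe()
            for r in range(n_repeats):
                for f in range(n_folds):
                    trace.append((cid, r, f, result.fold_scores[r, f]))
        cand = (-result.mean_score, key, cfg, result)
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None
    return best[2], best[3]


def _check_disjoint(train_rec: Recording, test_rec: Recording) -> None:
    if train_rec is test_rec:
        raise ValueError("leakage: training and test recordings are the same object")
    if (
        train_rec.recording_id is not None
        and train_rec.recording_id == test_rec.recording_id
    ):
        raise ValueError(
            f"leakage: training and test share recording id {train_rec.recording_id!r}"
        )
    if train_rec.signals.shape == test_rec.signals.shape and np.array_equal(
        train_rec.signals, test_rec.signals
    ):
        raise ValueError("leakage: training and test recordings contain identical signals")


def fit_final_and_test(
    config: PipelineConfig,
    train_recording: Recording,
    test_recording: Recording,
    label_map: Mapping[str, str] | None = None,
    train_intervals: Sequence[tuple[int, int]] | None = None,
    test_intervals: Sequence[tuple[int, int]] | None = None,
):
    """Refit the chosen pipeline on all training data and score the held-out set.

    Returns ``(score, outputs)`` where outputs are per-trial predicted labels
    (synchronous) or per-window :class:`ScoredWindows` (self-paced).  Raises a
    leakage error when training and test data are not disjoint.
    """
    _check_disjoint(train_recording, test_recording)
    selfpaced = train_intervals is not None
    if selfpaced:
        train_data, _ = _selfpaced_windows(train_recording, train_intervals, config)
        test_data, test_starts = _selfpaced_windows(test_recording, test_intervals, config)
    else:
        train_data = _sync_epochs(train_recording, label_map, config)
        test_data = _sync_epochs(test_recording, label_map, config)

    banded_tr = _banded(train_data, config)
    banded_te = _banded(test_data, config)
    spatial, model = _fit_on(banded_tr, config)
    if selfpaced:
        return _score_selfpaced(banded_te, spatial, model, config, test_starts)
    return _score_sync(banded_te, spatial, model, config)
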