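import numpy as np
import pytest

from bcibench.classifiers import ClassifierSpec, ParamGrid
from bcibench.core import Marker, Recording
from bcibench.evaluation import SlidingWindowConfig
from bcibench.model_selection import (
    CVResult,
    PipelineConfig,
    SearchSpace,
    crossval_score,
    fit_final_and_test,
    grid_search,
)
from bcibench.synthgen import SelfPacedConfig, SynthConfig, generate_selfpaced, generate_synchronous


def _lda_config(**kw):
    kw.setdefault("time_segment", (0.0, 3.0))
    return PipelineConfig(classifier=ClassifierSpec("LDA"), **kw)


@pytest.fixture(scope="module")
def nomod_recording():
    return generate_synchronous(
        SynthConfig(
            n_channels=4,
            sampling_rate=100.0,
            trials_per_class=30,
            trial_length_s=3.0,
            inter_trial_s=0.5,
            modulation={"left": (1.0, 1.0), "right": (1.0, 1.0)},
            seed=17,
        )
    )


class TestCrossvalScore:
    def test_separable_data_scores_high(self, erd_recording):
        res = crossval_score(_lda_config(), erd_recording, n_repeats=2, n_folds=5, seed=0)
        assert res.mean_score >= 0.9
        assert res.fold_scores.shape == (2, 5)

    def test_no_signal_scores_near_chance(self, nomod_recording):
        res = crossval_score(_lda_config(), nomod_recording, n_repeats=2, n_folds=5, seed=0)
        assert 0.4 <= res.mean_score <= 0.6

    def test_seeded_reproducibility(self, erd_recording):
        a = crossval_score(_lda_config(), erd_recording, n_repeats=2, n_folds=3, seed=4)
        b = crossval_score(_lda_config(), erd_recording, n_repeats=2, n_folds=3, seed=4)
        np.testing.assert_array_equal(a.fold_scores, b.fold_scores)

    def test_too_few_trials_per_class_rejected(self, erd_recording):
        with pytest.raises(ValueError, match="smallest class"):
            crossval_score(_lda_config(), erd_recording, n_folds=50)


class TestGridSearch:
    def test_single_config_space_returns_it(self, erd_recording):
        space = SearchSpace(
            classifier_grids={"LDA": ParamGrid("LDA")},
            time_segments=[(0.0, 3.0)],
            csp_pairs=[1],
        )
        best, cv = grid_search(space, erd_recording, n_repeats=1, n_folds=3, seed=0)
        assert best.classifier.kind == "LDA"
        assert best.time_segment == (0.0, 3.0)
        assert best.n_csp_pairs == 1
        assert isinstance(cv, CVResult)

    def test_planted_time_segment_recovered(self):
        """ERD lives inside the cue-to-2s trial; a candidate segment that
        dilutes it with pre-cue baseline should lose at realistic noise."""
        rec = generate_synchronous(
            SynthConfig(
                n_channels=4,
                sampling_rate=100.0,
                trials_per_class=30,
                trial_length_s=2.0,
                inter_trial_s=2.0,
                modulation={"left": (1.0, 1.0), "right": (0.3, 1.0)},
                noise_sd=3.0,
                seed=7,
            )
        )
        space = SearchSpace(
            classifier_grids={"LDA": ParamGrid("LDA")},
            time_segments=[(-2.0, 2.0), (0.0, 2.0)],
            csp_pairs=[1],
        )
        wins = 0
        for seed in range(3):
            best, _ = grid_search(space, rec, n_repeats=1, n_folds=3, seed=seed)
            if best.time_segment == (0.0, 2.0):
                wins += 1
        assert wins >= 2

    def test_tie_break_is_deterministic(self, erd_recording, monkeypatch):
        """With all scores equal, the winner is the earliest segment, fewest
        CSP pairs, lexicographically smallest parameters."""
        import bcibench.model_selection as ms

        def fake_cv(config, *a, **kw):
            return CVResult(0.5, np.full((1, 1), 0.5), config, 0, 1, 1)

        monkeypatch.setattr(ms, "crossval_score", fake_cv)
        space = SearchSpace(
            classifier_grids={"LR": ParamGrid("LR", {"C": [1.0, 0.01], "l1_ratio": [0.5]})},
            time_segments=[(0.5, 2.5), (0.0, 3.0)],
            csp_pairs=[2, 1],
        )
        best, _ = ms.grid_search(space, erd_recording, n_repeats=1, n_folds=1, seed=0)
        assert best.time_segment == (0.5, 2.5)
        assert best.n_csp_pairs == 1
        assert best.classifier.hyperparameters["C"] == 0.01

    def test_adding_configs_never_hurts(self, erd_recording):
        small = SearchSpace(
            classifier_grids={"LDA": ParamGrid("LDA")},
            time_segments=[(-0.5, 3.0)],
            csp_pairs=[1],
        )
        bigger = SearchSpace(
            classifier_grids={"LDA": ParamGrid("LDA")},
            time_segments=[(-0.5, 3.0), (0.0, 3.0)],
            csp_pairs=[1],
        )
        _, cv_small = grid_search(small, erd_recording, n_repeats=1, n_folds=3, seed=1)
        _, cv_big = grid_search(bigger, erd_recording, n_repeats=1, n_folds=3, seed=1)
        assert cv_big.mean_score >= cv_small.mean_score

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            SearchSpace(classifier_grids={})


class TestFitFinalAndTest:
    def test_train_equals_test_raises_leakage(self, erd_recording):
        with pytest.raises(ValueError, match="leakage"):
            fit_final_and_test(_lda_config(), erd_recording, erd_recording)

    def test_identical_signals_raise_leakage(self, erd_config):
        a = generate_synchronous(erd_config)
        b = generate_synchronous(erd_config)
        with pytest.raises(ValueError, match="leakage"):
            fit_final_and_test(_lda_config(), a, b)

    def test_separable_holdout(self, erd_config, erd_recording):
        from dataclasses import replace

        test_rec = generate_synchronous(replace(erd_config, session=1))
        acc, pred = fit_final_and_test(_lda_config(), erd_recording, test_rec)
        assert acc >= 0.85
        assert len(pred) == len(test_rec.markers)

    def test_corrupting_test_labels_leaves_predictions_unchanged(
        self, erd_config, erd_recording
    ):
        from dataclasses import replace

        test_rec = generate_selfcontained = generate_synchronous(replace(erd_config, session=1))
        _, pred = fit_final_and_test(_lda_config(), erd_recording, test_rec)
        flipped = Recording(
            signals=test_rec.signals,
            sampling_rate=test_rec.sampling_rate,
            channel_labels=list(test_rec.channel_labels),
            markers=[
                Marker(m.onset_sample, "left" if m.label == "right" else "right", m.duration_samples)
                for m in test_rec.markers
            ],
        )
        _, pred_flipped = fit_final_and_test(_lda_config(), erd_recording, flipped)
        np.testing.assert_array_equal(pred, pred_flipped)


class TestSelfPacedSelection:
    @pytest.fixture(scope="class")
    def selfpaced_pair(self):
        kw = dict(
            n_channels=3,
            sampling_rate=100.0,
            classes=("control",),
            modulation={"control": (0.25, 1.0)},
            total_length_s=120.0,
            seed=23,
        )
        train = generate_selfpaced(SelfPacedConfig(session=0, **kw))
        test = generate_selfpaced(SelfPacedConfig(session=1, **kw))
        return train, test

    def test_crossval_auc_above_chance(self, selfpaced_pair):
        (rec, intervals), _ = selfpaced_pair
        cfg = PipelineConfig(
            classifier=ClassifierSpec("LDA"),
            time_segment=None,
            window=SlidingWindowConfig(2.0, 0.5),
        )
        res = crossval_score(
            cfg, rec, control_intervals=intervals, n_repeats=1, n_folds=3, seed=0
        )
        assert res.mean_score >= 0.8

    def test_holdout_auc(self, selfpaced_pair):
        (tr, iv_tr), (te, iv_te) = selfpaced_pair
        cfg = PipelineConfig(
            classifier=ClassifierSpec("LDA"),
            time_segment=None,
            window=SlidingWindowConfig(2.0, 0.5),
        )
        score, scored = fit_final_and_test(
            cfg, tr, te, train_intervals=iv_tr, test_intervals=iv_te
        )
        assert score >= 0.8
        assert len(scored.scores) == len(scored.labels) == len(scored.window_starts)
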