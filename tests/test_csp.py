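import numpy as np
import pytest

from bcibench.core import EpochSet
from bcibench.csp import (
    CovariancePair,
    apply_csp,
    class_covariance,
    fit_csp,
    fit_csp_ovr,
    select_filters,
)


def _epochs(arrs, labels, fs=100.0):
    return EpochSet(np.asarray(arrs, dtype=float), np.asarray(labels, dtype=object), fs, (0, 1))


def _random_psd(rng, n, trace_one=True):
    A = rng.standard_normal((n, n))
    S = A @ A.T + 0.1 * np.eye(n)
    return S / np.trace(S) if trace_one else S


class TestClassCovariance:
    def test_white_noise_approaches_identity_over_n(self, rng):
        n_ch, n_trials = 4, 400
        es = _epochs(rng.standard_normal((n_trials, n_ch, 500)), ["a"] * n_trials)
        C = class_covariance(es, "a")
        assert abs(np.trace(C) - 1.0) < 1e-12
        # off-diagonals shrink as 1/sqrt(trials*samples); 3 SE bound
        se = 1.0 / np.sqrt(n_trials * 500) / n_ch
        assert np.all(np.abs(C - np.eye(n_ch) / n_ch) < 3 * se + 5e-3)

    def test_hand_computed_single_pair(self):
        # XX' = [[2,2],[2,2]], trace 4 -> all entries 0.5, trace exactly 1
        X = np.array([[1.0, -1.0], [1.0, -1.0]])
        es = _epochs([X, X], ["a", "a"])
        np.testing.assert_allclose(class_covariance(es, "a"), np.full((2, 2), 0.5))

    def test_absent_label_rejected(self, random_epochs):
        with pytest.raises(ValueError, match="no trials"):
            class_covariance(random_epochs, "nonexistent")

    def test_zero_trial_rejected(self):
        es = _epochs([np.zeros((2, 10)), np.ones((2, 10))], ["a", "a"])
        with pytest.raises(ValueError, match="degenerate"):
            class_covariance(es, "a")


class TestFitCsp:
    def test_equal_covariances_give_half_eigenvalues(self, rng):
        S = _random_psd(rng, 4)
        f = fit_csp(CovariancePair(S, S))
        np.testing.assert_allclose(f.eigenvalues, 0.5, atol=1e-10)

    def test_diagonal_pair_solved_exactly(self):
        sp = np.diag([0.8, 0.2])
        sn = np.diag([0.2, 0.8])
        f = fit_csp(CovariancePair(sp, sn))
        np.testing.assert_allclose(f.eigenvalues, [0.8, 0.2], atol=1e-12)
        # filters along coordinate axes (up to scale)
        W = np.abs(f.W / np.abs(f.W).max(axis=1, keepdims=True))
        np.testing.assert_allclose(W, np.eye(2), atol=1e-10)

    def test_whitening_normalisation(self, rng):
        sp, sn = _random_psd(rng, 5), _random_psd(rng, 5)
        f = fit_csp(CovariancePair(sp, sn))
        for w, lam in zip(f.W, f.eigenvalues):
            assert abs(w @ (sp + sn) @ w - 1.0) < 1e-6
            assert abs(w @ sp @ w - lam) < 1e-6
        assert np.all(np.diff(f.eigenvalues) <= 1e-12)

    def test_top_eigenvalue_beats_random_rayleigh_quotients(self, rng):
        sp, sn = _random_psd(rng, 4), _random_psd(rng, 4)
        f = fit_csp(CovariancePair(sp, sn))
        w = rng.standard_normal((10_000, 4))
        num = np.einsum("ij,jk,ik->i", w, sp, w)
        den = num + np.einsum("ij,jk,ik->i", w, sn, w)
        q = num / den
        assert f.eigenvalues[0] >= q.max() - 1e-9
        assert f.eigenvalues[-1] <= q.min() + 1e-9

    def test_label_swap_antisymmetry(self, rng):
        sp, sn = _random_psd(rng, 4), _random_psd(rng, 4)
        a = fit_csp(CovariancePair(sp, sn))
        b = fit_csp(CovariancePair(sn, sp))
        np.testing.assert_allclose(b.eigenvalues, (1 - a.eigenvalues)[::-1], atol=1e-8)

    def test_channel_permutation_invariance(self, rng):
        sp, sn = _random_psd(rng, 4), _random_psd(rng, 4)
        perm = np.array([2, 0, 3, 1])
        a = fit_csp(CovariancePair(sp, sn))
        b = fit_csp(CovariancePair(sp[np.ix_(perm, perm)], sn[np.ix_(perm, perm)]))
        np.testing.assert_allclose(b.eigenvalues, a.eigenvalues, atol=1e-8)
        np.testing.assert_allclose(b.W, a.W[:, perm], atol=1e-6)

    def test_scale_invariance_via_normalised_covariances(self, rng):
        es = EpochSet(rng.standard_normal((10, 3, 200)), np.array(["a", "b"] * 5, dtype=object), 100.0, (0, 2))
        scaled = EpochSet(es.epochs * 17.0, es.labels, 100.0, (0, 2))
        pair = lambda e: CovariancePair(class_covariance(e, "a"), class_covariance(e, "b"))
        a, b = fit_csp(pair(es)), fit_csp(pair(scaled))
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(a.W, b.W, atol=1e-8)


class TestSelectFilters:
    def test_symmetric_extremes_kept(self, rng):
        sp, sn = _random_psd(rng, 6), _random_psd(rng, 6)
        f = fit_csp(CovariancePair(sp, sn))
        sel = select_filters(f, 1)
        np.testing.assert_allclose(
            sel.eigenvalues, [f.eigenvalues[0], f.eigenvalues[-1]]
        )

    def test_full_selection_is_identity(self, rng):
        sp, sn = _random_psd(rng, 4), _random_psd(rng, 4)
        f = fit_csp(CovariancePair(sp, sn))
        sel = select_filters(f, 2)
        np.testing.assert_allclose(sel.W, f.W)

    def test_explicit_lambda_ordering(self):
        from bcibench.csp import SpatialFilterSet

        f = SpatialFilterSet(
            W=np.eye(5), eigenvalues=np.array([0.9, 0.7, 0.5, 0.3, 0.1]), class_pair=("+", "-")
        )
        sel = select_filters(f, 2)
        np.testing.assert_allclose(sel.eigenvalues, [0.9, 0.7, 0.3, 0.1])

    def test_oversized_selection_rejected(self, rng):
        sp, sn = _random_psd(rng, 4), _random_psd(rng, 4)
        with pytest.raises(ValueError):
            select_filters(fit_csp(CovariancePair(sp, sn)), 3)


class TestApplyCsp:
    def test_identity_projection(self, random_epochs):
        from bcibench.csp import SpatialFilterSet

        f = SpatialFilterSet(np.eye(4), np.linspace(1, 0, 4), ("+", "-"))
        out = apply_csp(f, random_epochs)
        np.testing.assert_array_equal(out.epochs, random_epochs.epochs)

    def test_class_variances_sum_to_one_after_whitening(self, rng):
        es = EpochSet(
            rng.standard_normal((40, 3, 300)),
            np.array(["a", "b"] * 20, dtype=object),
            100.0,
            (0, 3),
        )
        centered = es.epochs - es.epochs.mean(axis=2, keepdims=True)
        es = EpochSet(centered, es.labels, 100.0, (0, 3))
        pair = CovariancePair(class_covariance(es, "a"), class_covariance(es, "b"))
        f = fit_csp(pair)
        proj = apply_csp(f, es)
        # normalised per-trial variance share, averaged per class, sums to 1
        va = np.mean(
            [np.diag(proj.epochs[i] @ proj.epochs[i].T / np.trace(es.epochs[i] @ es.epochs[i].T))
             for i in np.flatnonzero(es.labels == "a")], axis=0)
        vb = np.mean(
            [np.diag(proj.epochs[i] @ proj.epochs[i].T / np.trace(es.epochs[i] @ es.epochs[i].T))
             for i in np.flatnonzero(es.labels == "b")], axis=0)
        np.testing.assert_allclose(va + vb, 1.0, atol=1e-10)

    def test_surrogate_channel_count(self, rng):
        es = EpochSet(rng.standard_normal((5, 22, 100)), np.array(["a"] * 5, dtype=object), 100.0, (0, 1))
        from bcibench.csp import SpatialFilterSet

        f = SpatialFilterSet(rng.standard_normal((2, 22)), np.array([0.9, 0.1]), ("+", "-"))
        assert apply_csp(f, es).n_channels == 2

    def test_dimension_mismatch_rejected(self, random_epochs):
        from bcibench.csp import SpatialFilterSet

        f = SpatialFilterSet(np.eye(7), np.linspace(1, 0, 7), ("+", "-"))
        with pytest.raises(ValueError, match="channels"):
            apply_csp(f, random_epochs)


class TestOneAgainstOthers:
    def test_two_class_symmetry(self, rng):
        es = EpochSet(
            rng.standard_normal((20, 3, 200)),
            np.array(["a", "b"] * 10, dtype=object),
            100.0,
            (0, 2),
        )
        sets = fit_csp_ovr(es)
        assert len(sets) == 2
        np.testing.assert_allclose(
            sets[1].eigenvalues, (1 - sets[0].eigenvalues)[::-1], atol=1e-8
        )

    def test_four_class_design(self, rng):
        labels = np.array(["feet", "left", "right", "tongue"] * 8, dtype=object)
        es = EpochSet(rng.standard_normal((32, 5, 150)), labels, 100.0, (0, 1.5))
        sets = fit_csp_ovr(es)
        assert [s.class_pair[0] for s in sets] == ["feet", "left", "right", "tongue"]

    def test_single_class_rejected(self, rng):
        es = EpochSet(rng.standard_normal((4, 3, 100)), np.array(["a"] * 4, dtype=object), 100.0, (0, 1))
        with pytest.raises(ValueError, match="2 classes"):
            fit_csp_ovr(es)
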