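"""Common Spatial Patterns (CSP).

CSP is a supervised linear spatial filter for two-class oscillatory EEG.  Given
trial-averaged normalised covariance matrices of the two classes, Sigma+ and
Sigma-, it finds projection directions ``w`` that maximise the variance share

    w Sigma+ w' / (w Sigma+ w' + w Sigma- w')

by simultaneous diagonalisation of the two covariances: whiten by the composite
``Sigma+ + Sigma-`` and eigendecompose the whitened Sigma+.  The resulting
eigenvalues lie in [0, 1]; filters with extreme eigenvalues concentrate one
class's band power and are the informative "surrogate channels".  Multiclass
problems use a one-against-others scheme, fitting one filter set per class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .core import EpochSet

__all__ = [
    "CovariancePair",
    "SpatialFilterSet",
    "trial_covariance",
    "class_covariance",
    "fit_csp",
    "select_filters",
    "apply_csp",
    "fit_csp_ovr",
]

#: Relative ridge added to the composite covariance before whitening; guards
#: against rank deficiency after zero-phase narrow-band filtering.
RIDGE = 1e-10


@dataclass(frozen=True)
class CovariancePair:
    """Trace-normalised class covariance matrices (positive class, negative/rest)."""

    sigma_pos: np.ndarray
    sigma_neg: np.ndarray

    def __post_init__(self) -> None:
        for name, s in (("sigma_pos", self.sigma_pos), ("sigma_neg", self.sigma_neg)):
            s = np.asarray(s)
            if s.ndim != 2 or s.shape[0] != s.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(s, s.T, atol=1e-10):
                raise ValueError(f"{name} is not symmetric")
        if self.sigma_pos.shape != self.sigma_neg.shape:
            raise ValueError("class covariances must have equal dimensions")


@dataclass(frozen=True)
class SpatialFilterSet:
    """CSP projection: rows of W are filters, ordered by descending eigenvalue.

    Each filter satisfies ``w Sigma+ w' = lambda`` and
    ``w (Sigma+ + Sigma-) w' = 1`` (whitening normalisation).
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    class_pair: tuple[str, str]

    @property
    def n_components(self) -> int:
        return self.W.shape[0]


def trial_covariance(trial: np.ndarray) -> np.ndarray:
    """Normalised single-trial covariance ``X X' / trace(X X')``."""
    c = trial @ trial.T
    t = np.trace(c)
    if t <= 0:
        raise ValueError("degenerate trial: zero signal (covariance trace 0)")
    return c / t


def class_covariance(epochs: EpochSet, label: str) -> np.ndarray:
    """Mean of normalised trial covariances over all trials of ``label``."""
    mask = epochs.labels == label
    if not mask.any():
        raise ValueError(f"no trials with label {label!r}")
    if mask.sum() < 2:
        raise ValueError(f"class {label!r} needs >= 2 trials, has {int(mask.sum())}")
    covs = []
    for i in np.flatnonzero(mask):
        try:
            covs.append(trial_covariance(epochs.epochs[i]))
        except ValueError as e:
            raise ValueError(f"trial {i}: {e}") from None
    return np.mean(covs, axis=0)


def _pooled_covariance(epochs: EpochSet, labels) -> np.ndarray:
    """Trialwise-pooled covariance over every trial whose label is in ``labels``."""
    mask = np.isin(epochs.labels, list(labels))
    if mask.sum() < 2:
        raise ValueError("pooled rest class needs >= 2 trials")
    return np.mean([trial_covariance(epochs.epochs[i]) for i in np.flatnonzero(mask)], axis=0)


def fit_csp(cov: CovariancePair, class_pair: tuple[str, str] = ("+", "-")) -> SpatialFilterSet:
    """Solve the CSP eigenproblem for one covariance pair.

    Whitens by the composite covariance (plus a tiny ridge), eigendecomposes
    the whitened Sigma+, and returns filters sorted by descending eigenvalue.
    Each filter's largest-magnitude coefficient is made positive so the output
    is deterministic across linear-algebra backends.
    """
    sp = np.asarray(cov.sigma_pos, dtype=np.float64)
    sn = np.asarray(cov.sigma_neg, dtype=np.float64)
    comp = sp + sn
    comp = comp + RIDGE * np.trace(comp) * np.eye(comp.shape[0])

    d, V = linalg.eigh(comp)
    if d[0] <= 0:
        raise np.linalg.LinAlgError(
            "composite covariance is not positive definite even after ridge"
        )
    # symmetric whitener P with P comp P' = I
    P = V @ np.diag(1.0 / np.sqrt(d)) @ V.T
    lam, U = linalg.eigh(P @ sp @ P.T)
    lam = np.clip(lam, 0.0, 1.0)

    order = np.argsort(lam, kind="stable")[::-1]
    lam = lam[order]
    W = (U.T @ P)[order]
    # sign convention: largest-magnitude coefficient positive
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    W = W * signs[:, None]
    return SpatialFilterSet(W=W, eigenvalues=lam, class_pair=class_pair)


def select_filters(filters: SpatialFilterSet, n_pairs: int) -> SpatialFilterSet:
    """Keep the ``n_pairs`` most extreme filters from each end of the spectrum.

    Rows stay in descending-eigenvalue order; the top rows favour the positive
    class's variance, the bottom rows the negative class's.
    """
    k = filters.n_components
    if 2 * n_pairs > k:
        raise ValueError(f"cannot select {n_pairs} pairs from {k} components")
    keep = list(range(n_pairs)) + list(range(k - n_pairs, k))
    return SpatialFilterSet(
        W=filters.W[keep],
        eigenvalues=filters.eigenvalues[keep],
        class_pair=filters.class_pair,
    )


def apply_csp(filters: SpatialFilterSet, epochs: EpochSet) -> EpochSet:
    """Project every trial into the surrogate-channel space: X -> W X."""
    if epochs.n_channels != filters.W.shape[1]:
        raise ValueError(
            f"filter set expects {filters.W.shape[1]} channels, epochs have "
            f"{epochs.n_channels}"
        )
    projected = np.einsum("ij,tjk->tik", filters.W, epochs.epochs)
    names = [f"csp{i}" for i in range(filters.n_components)]
    return replace(epochs, epochs=projected, channel_labels=names)


def fit_csp_ovr(epochs: EpochSet, labels=None) -> list[SpatialFilterSet]:
    """One-against-others CSP: one filter set per class, in sorted label order.

    For each class the positive covariance is that class's mean normalised
    trial covariance and the negative is the trialwise-pooled covariance of all
    remaining classes.
    """
    classes = np.unique(epochs.labels) if labels is None else np.asarray(labels)
    if len(classes) < 2:
        raise ValueError(f"one-against-others CSP needs >= 2 classes, got {len(classes)}")
    out = []
    for c in classes:
        rest = [r for r in classes if r != c]
        pair = CovariancePair(
            sigma_pos=class_covariance(epochs, c),
            sigma_neg=_pooled_covariance(epochs, rest),
        )
        out.append(fit_csp(pair, class_pair=(str(c), "rest")))
    return out
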