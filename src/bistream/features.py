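"""Spatio-temporal SVD feature reduction.

Single trials are reduced, without reference to their labels, to the leading
k_spatial spatial modes of the pooled data and then to the leading k_temporal
temporal modes of the spatially projected data, giving
k_spatial * k_temporal coefficients per trial (25 at the defaults).  Class
counts are balanced beforehand by subsampling the more frequent percept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "balance_trials",
    "spatial_modes",
    "temporal_modes",
    "build_features",
]


@dataclass
class FeatureMatrix:
    """Trials x (k_spatial * k_temporal) feature matrix with labels.

    ``X`` rows are spatial-major flattenings of the per-trial coefficient
    matrix; ``spatial_basis`` (channels x k_s) and ``temporal_basis``
    (samples x k_t) are orthonormal; ``selected_trials`` indexes into the
    retained-trial array the features were built from.
    """

    X: np.ndarray
    y: np.ndarray
    spatial_basis: np.ndarray | None
    temporal_basis: np.ndarray
    selected_trials: np.ndarray


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic SVD sign convention: each basis vector's
    largest-magnitude element is made positive."""
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    return U * flip


def balance_trials(
    labels: np.ndarray, scheme: str = "spread", seed: int | None = None
) -> np.ndarray:
    """Indices giving equal class counts (minority count per class).

    "spread" subsamples the majority class at evenly spaced positions over
    its chronological order (deterministic); "sequential" keeps its first n
    trials.  Returned indices are sorted chronologically.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if counts.min() == 0:
        raise ValueError("a class has no trials")
    n = int(counts.min())
    keep = []
    for c, cnt in zip(classes, counts):
        idx = np.flatnonzero(labels == c)
        if cnt == n:
            keep.append(idx)
        elif scheme == "spread":
            pos = np.round(np.linspace(0, cnt - 1, n)).astype(int)
            keep.append(idx[pos])
        elif scheme == "sequential":
            keep.append(idx[:n])
        else:
            raise ValueError(f"unknown balancing scheme {scheme!r}")
    return np.sort(np.concatenate(keep))


def spatial_modes(
    data: np.ndarray, k: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading spatial SVD modes of pooled trials.

    The (trials, channels, samples) array is unfolded to
    channels x (trials*samples); the first k left singular vectors form the
    spatial basis.  Returns (basis channels x k, projected trials x k x
    samples, singular values).
    """
    n_trials, n_ch, n_samp = data.shape
    if n_ch < k:
        logger.warning("k=%d exceeds channel count %d; reducing", k, n_ch)
        k = n_ch
    unfolded = np.transpose(data, (1, 0, 2)).reshape(n_ch, n_trials * n_samp)
    U, s, _ = np.linalg.svd(unfolded, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < k:
        logger.warning("data rank %d below k=%d; reducing", rank, k)
        k = max(rank, 1)
    U = _fix_signs(U[:, :k])
    projected = np.einsum("ck,tcs->tks", U, data)
    return U, projected, s


def temporal_modes(
    projected: np.ndarray, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Leading temporal SVD modes of the pooled projected data.

    The (trials, k_spatial, samples) array is unfolded to
    (trials*k_spatial) x samples; the first k right singular vectors form
    the temporal basis.  Each trial's coefficient matrix
    (k_spatial x k) is flattened spatial-major into the feature rows.
    Returns (basis samples x k, X trials x (k_spatial*k)).
    """
    n_trials, k_s, n_samp = projected.shape
    if n_samp < k:
        logger.warning("k=%d exceeds sample count %d; reducing", k, n_samp)
        k = n_samp
    unfolded = projected.reshape(n_trials * k_s, n_samp)
    _, s, Vt = np.linalg.svd(unfolded, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if rank < k:
        logger.warning("data rank %d below k=%d; reducing", rank, k)
        k = max(rank, 1)
    V = _fix_signs(Vt[:k].T)
    X = np.einsum("tks,sj->tkj", projected, V).reshape(n_trials, k_s * k)
    return V, X


def build_features(
    data: np.ndarray,
    labels: np.ndarray,
    k_spatial: int = 5,
    k_temporal: int = 5,
    balance: str = "spread",
    seed: int | None = None,
) -> FeatureMatrix:
    """Balanced spatio-temporal feature matrix from retained trials.

    ``data`` is (trials, channels, samples) with per-trial ``labels``; both
    bases are computed from the pooled (both-condition) balanced trials only,
    so the unsupervised reduction never sees the labels.
    """
    sel = balance_trials(labels, scheme=balance, seed=seed)
    sub = data[sel]
    if sub.shape[1] == 1:  # single source: temporal reduction only
        sbasis = None
        projected = sub
    else:
        sbasis, projected, _ = spatial_modes(sub, k_spatial)
    tbasis, X = temporal_modes(projected, k_temporal)
    return FeatureMatrix(
        X=X,
        y=np.asarray(labels)[sel],
        spatial_basis=sbasis,
        temporal_basis=tbasis,
        selected_trials=sel,
    )
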