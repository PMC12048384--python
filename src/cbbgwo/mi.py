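"""Plug-in mutual-information analysis of a feature matrix.

Continuous tripeptide frequencies are discretised by equal-frequency
binning (deterministic tie handling: tied values share the lower bin) and
mutual information is estimated from empirical joint counts, in bits.
Three algebraically equivalent forms are implemented and cross-checked in
the test suite: the direct double sum over the joint distribution, the
entropy identity I(X;Y) = H(X) + H(Y) - H(X,Y), and the expectation of
the pointwise mutual information.

``pairwise_mi_matrix`` computes the full symmetric feature-by-feature MI
matrix.  Because a small dataset leaves many of the 8000 tripeptide
columns identically zero, an all-zero-column screen runs first; the map
back to original 1-based feature indices is kept so every report stays in
the 1...8000 coordinate system.  The pair computation is vectorised as
one bin-indicator matrix product per bin pair, which keeps the d^2 loop
inside BLAS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import FeatureMatrix, index_to_tripeptide


def discretize(values: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Equal-frequency binning with ties sharing the lower bin.

    Returns integer codes in ``[0, n_bins)``.  A constant vector maps to
    the single code 0.  ``n_bins`` larger than the sample count is
    clamped with a warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1:
        raise ValueError("discretize expects a 1-D vector")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n = values.size
    if n_bins > n:
        warnings.warn(f"n_bins={n_bins} > n={n}; clamping to {n}",
                      stacklevel=2)
        n_bins = n
    order = np.argsort(values, kind="stable")
    provisional = np.empty(n, dtype=np.int64)
    provisional[order] = (np.arange(n) * n_bins) // n
    # tied values all take the lowest provisional code of their tie group
    sorted_vals = values[order]
    group_start = np.empty(n, dtype=bool)
    group_start[0] = True
    group_start[1:] = sorted_vals[1:] != sorted_vals[:-1]
    group_id = np.cumsum(group_start) - 1
    group_min = np.minimum.reduceat(provisional[order],
                                    np.flatnonzero(group_start))
    codes = np.empty(n, dtype=np.int64)
    codes[order] = group_min[group_id]
    return codes


def joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Empirical joint count table of two integer code vectors."""
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("code vectors must be 1-D and of equal length")
    bx, by = int(x.max()) + 1, int(y.max()) + 1
    return np.bincount(x * by + y, minlength=bx * by).reshape(bx, by)


def entropy(probabilities: np.ndarray) -> float:
    """Shannon entropy in bits, with 0 log 0 = 0.

    Accepts a marginal or (flattened) joint probability vector; the
    probabilities must be non-negative and sum to one.
    """
    p = np.asarray(probabilities, dtype=np.float64).ravel()
    if (p < 0).any():
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mi_from_joint(counts: np.ndarray, method: str = "direct") -> float:
    """Mutual information in bits from a joint count (or probability) table.

    ``method`` selects one of three equivalent computations:
    ``"direct"`` (double sum over joint cells), ``"entropy"``
    (H(X) + H(Y) - H(X,Y)) or ``"pmi"`` (joint-weighted mean of pointwise
    mutual information).  All agree to within numerical round-off.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or (counts < 0).any():
        raise ValueError("need a non-negative 2-D count table")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty count table")
    p = counts / total
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    if method == "entropy":
        return entropy(px) + entropy(py) - entropy(p)
    mask = p > 0
    ratio = p[mask] / np.outer(px, py)[mask]
    if method == "direct":
        return float((p[mask] * np.log2(ratio)).sum())
    if method == "pmi":
        pmi = np.log2(ratio)
        return float(np.dot(p[mask], pmi))
    raise ValueError(f"unknown method {method!r}")


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI in bits between two integer code vectors (plug-in estimate)."""
    return mi_from_joint(joint_counts(x, y), method="direct")


@dataclass
class MIMatrix:
    """Symmetric pairwise MI matrix over the retained feature set.

    ``values[i, j]`` is I(f_i; f_j) in bits for retained features i, j;
    the diagonal holds the per-feature plug-in entropy H(f_i).
    ``feature_indices`` maps retained columns back to original 1-based
    feature indices.
    """

    values: np.ndarray
    feature_indices: np.ndarray
    n_bins: int
    estimator: str = "plug-in/equal-frequency"
    codes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or \
                self.values.shape[0] != self.values.shape[1]:
            raise ValueError("MI matrix must be square")
        if len(self.feature_indices) != self.values.shape[0]:
            raise ValueError("feature index map must match matrix size")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        names = [index_to_tripeptide(int(i)) for i in self.feature_indices]
        pd.DataFrame(self.values, index=names, columns=names).to_csv(
            path, sep="\t")


def _bin_indicators(codes: np.ndarray, n_bins: int) -> list[np.ndarray]:
    return [(codes == b).astype(np.float32) for b in range(n_bins)]


def discretize_matrix(matrix: FeatureMatrix, n_bins: int = 5,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Screen out all-zero columns and discretise the rest.

    Returns ``(codes, feature_indices)`` where ``codes`` is n x d_retained
    integer codes and ``feature_indices`` the original 1-based indices of
    the retained columns.
    """
    values = matrix.values
    nonzero = np.flatnonzero((values != 0).any(axis=0))
    if nonzero.size == 0:
        raise ValueError("all features are identically zero")
    codes = np.empty((values.shape[0], nonzero.size), dtype=np.int8)
    for k, j in enumerate(nonzero):
        codes[:, k] = discretize(values[:, j], n_bins)
    return codes, nonzero + 1


def pairwise_mi_matrix(matrix: FeatureMatrix, n_bins: int = 5) -> MIMatrix:
    """Pairwise MI (bits) between all retained features.

    Uses the factorisation
    I_ij = S_ij / n + log2(n) - P_i / n - Q_j / n with
    S_ij = sum_ab C_ab log2 C_ab over joint counts and P, Q the marginal
    count-entropy sums, so only the S term needs one d x d product per
    bin pair.  The result is symmetrised to remove float round-off
    asymmetry from the BLAS accumulation order.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples for pairwise MI")
    codes, feature_indices = discretize_matrix(matrix, n_bins)
    eff_bins = int(codes.max()) + 1
    indicators = _bin_indicators(codes, eff_bins)
    d = codes.shape[1]

    S = np.zeros((d, d), dtype=np.float32)
    for a in range(eff_bins):
        Ia = indicators[a]
        for b in range(eff_bins):
            C = Ia.T @ indicators[b]
            with np.errstate(divide="ignore", invalid="ignore"):
                L = np.log2(C, where=C > 0, out=np.zeros_like(C))
            L *= C
            S += L
    marg = np.stack([ind.sum(axis=0) for ind in indicators])  # bins x d
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.log2(marg, where=marg > 0, out=np.zeros_like(marg))
    P = (marg * lm).sum(axis=0).astype(np.float64)  # per-feature

    mi = S.astype(np.float64) / n
    mi += np.log2(n)
    mi -= P[:, None] / n
    mi -= P[None, :] / n
    mi = (mi + mi.T) / 2.0
    np.clip(mi, 0.0, None, out=mi)
    return MIMatrix(values=mi, feature_indices=feature_indices,
                    n_bins=n_bins, codes=codes)


def relevance_to_label(matrix: FeatureMatrix,
                       labels: np.ndarray | None = None,
                       n_bins: int = 5,
                       codes: np.ndarray | None = None,
                       feature_indices: np.ndarray | None = None,
                       ) -> pd.Series:
    """I(feature; class label) in bits for every retained feature.

    Returns a Series indexed by original 1-based feature index.  With a
    single class every relevance is zero (a warning is emitted).  The
    discretised codes can be passed in to avoid re-binning.
    """
    if labels is None:
        labels = matrix.labels
    labels = np.asarray(labels)
    if codes is None:
        codes, feature_indices = discretize_matrix(matrix, n_bins)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        warnings.warn("single class: all relevances are zero", stacklevel=2)
        return pd.Series(np.zeros(codes.shape[1]), index=feature_indices)
    rel = np.empty(codes.shape[1], dtype=np.float64)
    for k in range(codes.shape[1]):
        rel[k] = mutual_information(codes[:, k], y)
    return pd.Series(rel, index=np.asarray(feature_indices))
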