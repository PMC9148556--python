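"""User-based similarity weights between patient feature vectors.

Five measures are supported, named by the usual collaborative-filtering
abbreviations (case-insensitive):

``pcc``
    Pearson correlation coefficient,
    sum((x-mean x)(y-mean y)) / (||x-mean x|| ||y-mean y||).
``mrc``
    Median-based robust correlation: the Pearson formula with the medians
    substituted for the means, robust to outlying features.
``cos``
    Cosine similarity, sum(x y) / (||x|| ||y||).
``man``
    Manhattan distance similarity, 1 / sum(|x - y|).
``euc``
    Euclidean distance similarity, 1 / sqrt(sum((x - y)^2)).

Correlation-type weights live in [-1, +1]; distance-type weights are
positive, and two identical vectors produce an *infinite* sentinel which
:func:`resolve_infinite` replaces by the largest finite weight in the
matrix.

Vectors with missing entries are compared pairwise-complete: only feature
positions observed in **both** samples enter a pair's weight, and a pair
with fewer than ``min_overlap`` common features (or an undefined
denominator, e.g. a zero-variance vector under ``pcc``) is marked invalid
and excluded from neighbor candidacy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MEASURES",
    "DISTANCE_MEASURES",
    "CORRELATION_MEASURES",
    "SimilarityWeight",
    "SimilarityMatrix",
    "pairwise_complete",
    "similarity",
    "similarity_matrix",
    "resolve_infinite",
]

CORRELATION_MEASURES = ("pcc", "mrc", "cos")
DISTANCE_MEASURES = ("man", "euc")
MEASURES = CORRELATION_MEASURES + DISTANCE_MEASURES

_EPS_DENOM = 1e-12


def canonical_measure(measure: str) -> str:
    m = measure.strip().lower()
    if m not in MEASURES:
        raise ValueError(f"unknown similarity measure {measure!r}; choose one of {MEASURES}")
    return m


@dataclass(frozen=True)
class SimilarityWeight:
    """One pairwise weight: value, measure, overlap size, validity flags."""

    value: float
    measure: str
    n_overlap: int
    valid: bool = True
    infinite: bool = False


@dataclass
class SimilarityMatrix:
    """Square symmetric grid of pairwise weights over samples.

    ``weights[i, j]`` is NaN when the pair is invalid (insufficient
    overlap or undefined denominator) and +inf while an unresolved
    identical-vector sentinel is present (distance measures only). The
    diagonal is NaN (a sample is never its own neighbor).
    """

    weights: np.ndarray
    measure: str
    n_overlap: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]


def pairwise_complete(
    x: np.ndarray,
    y: np.ndarray,
    x_mask: np.ndarray | None = None,
    y_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Restrict two feature vectors to positions observed in both.

    Masks default to ``isfinite`` of the values. Returns the aligned
    sub-vectors and the overlap count; raises when the overlap is empty.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    x_mask = np.isfinite(x) if x_mask is None else np.asarray(x_mask, bool)
    y_mask = np.isfinite(y) if y_mask is None else np.asarray(y_mask, bool)
    common = x_mask & y_mask
    n = int(common.sum())
    if n == 0:
        raise ValueError("similarity undefined: disjoint observation patterns (no common features)")
    return x[common], y[common], n


def similarity(
    x: np.ndarray,
    y: np.ndarray,
    measure: str,
    min_overlap: int = 2,
) -> SimilarityWeight:
    """Similarity weight between two (already pairwise-complete or fully
    observed) vectors.

    Missing entries are removed pairwise-complete first. Returns an
    invalid weight (NaN value) when the overlap is below ``min_overlap``
    or the measure's denominator vanishes; returns an infinite sentinel
    for identical vectors under a distance measure.
    """
    measure = canonical_measure(measure)
    xs, ys, n = pairwise_complete(x, y)
    if n < min_overlap:
        return SimilarityWeight(np.nan, measure, n, valid=False)

    if measure in ("pcc", "mrc"):
        center = np.mean if measure == "pcc" else np.median
        dx = xs - center(xs)
        dy = ys - center(ys)
        den = np.sqrt(np.sum(dx * dx)) * np.sqrt(np.sum(dy * dy))
        if den <= _EPS_DENOM:
            return SimilarityWeight(np.nan, measure, n, valid=False)
        return SimilarityWeight(float(np.sum(dx * dy) / den), measure, n)
    if measure == "cos":
        den = np.sqrt(np.sum(xs * xs)) * np.sqrt(np.sum(ys * ys))
        if den <= _EPS_DENOM:
            return SimilarityWeight(np.nan, measure, n, valid=False)
        return SimilarityWeight(float(np.sum(xs * ys) / den), measure, n)
    if measure == "man":
        d = float(np.sum(np.abs(xs - ys)))
    else:  # euc
        d = float(np.sqrt(np.sum((xs - ys) ** 2)))
    if d == 0.0:
        return SimilarityWeight(np.inf, measure, n, infinite=True)
    return SimilarityWeight(1.0 / d, measure, n)


def similarity_matrix(
    X: np.ndarray,
    measure: str,
    mask: np.ndarray | None = None,
    min_overlap: int = 2,
    chunk_bytes: int = 64_000_000,
) -> SimilarityMatrix:
    """All pairwise weights over the rows of ``X`` (samples x features).

    Vectorized pairwise-complete computation; NaN cells in ``X`` (or
    ``mask = False``) are excluded per pair. Invalid pairs get NaN,
    identical-vector pairs under a distance measure get +inf (resolve with
    :func:`resolve_infinite`). The diagonal is NaN.
    """
    measure = canonical_measure(measure)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    O = np.isfinite(X) if mask is None else (np.asarray(mask, bool) & np.isfinite(X))
    Xn = np.where(O, X, np.nan)
    n_overlap = (O.astype(np.int64) @ O.T.astype(np.int64))
    W = np.full((n, n), np.nan)

    rows_per_chunk = max(1, int(chunk_bytes // max(1, 8 * n * p)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means/medians
        for i0 in range(0, n, rows_per_chunk):
            i1 = min(n, i0 + rows_per_chunk)
            common = O[i0:i1, None, :] & O[None, :, :]
            Xi = np.where(common, X[i0:i1, None, :], np.nan)
            Yi = np.where(common, X[None, :, :], np.nan)
            if measure in ("pcc", "mrc"):
                center = np.nanmean if measure == "pcc" else np.nanmedian
                dx = Xi - center(Xi, axis=2, keepdims=True)
                dy = Yi - center(Yi, axis=2, keepdims=True)
                num = np.nansum(dx * dy, axis=2)
                den = np.sqrt(np.nansum(dx * dx, axis=2)) * np.sqrt(np.nansum(dy * dy, axis=2))
                block = np.where(den > _EPS_DENOM, num / np.where(den > 0, den, 1.0), np.nan)
            elif measure == "cos":
                num = np.nansum(Xi * Yi, axis=2)
                den = np.sqrt(np.nansum(Xi * Xi, axis=2)) * np.sqrt(np.nansum(Yi * Yi, axis=2))
                block = np.where(den > _EPS_DENOM, num / np.where(den > 0, den, 1.0), np.nan)
            else:
                if measure == "man":
                    d = np.nansum(np.abs(Xi - Yi), axis=2)
                else:
                    d = np.sqrt(np.nansum((Xi - Yi) ** 2, axis=2))
                block = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), np.inf)
            W[i0:i1, :] = block

    W[n_overlap < max(1, min_overlap)] = np.nan
    np.fill_diagonal(W, np.nan)
    return SimilarityMatrix(W, measure, n_overlap)


def resolve_infinite(sm: SimilarityMatrix, per_row: bool = False) -> SimilarityMatrix:
    """Replace infinite identical-vector sentinels by the highest finite
    weight (matrix-wide by default, per row with ``per_row=True``).

    Raises when every defined pair is infinite (degenerate cohort of
    identical samples).
    """
    W = sm.weights.copy()
    inf = np.isinf(W)
    if not inf.any():
        return SimilarityMatrix(W, sm.measure, sm.n_overlap)
    finite = np.isfinite(W)
    if not finite.any():
        raise ValueError("degenerate cohort: all defined pairs have infinite similarity")
    if per_row:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row_max = np.nanmax(np.where(finite, W, np.nan), axis=1)
        global_max = W[finite].max()
        row_max = np.where(np.isfinite(row_max), row_max, global_max)
        W[inf] = np.broadcast_to(row_max[:, None], W.shape)[inf]
    else:
        W[inf] = W[finite].max()
    return SimilarityMatrix(W, sm.measure, sm.n_overlap)
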