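"""Reference imputers: zero fill, column mean / winsorized mean / median,
and iterative low-rank matrix completion (LRMC).

A plug-in slot (:func:`impute_with`) accepts any external callable mapping
a masked value grid to a filled grid, for parity experiments with methods
not implemented here (e.g. regularized EM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats.mstats import winsorize

from .data_model import FeatureMatrix

__all__ = ["BASELINE_METHODS", "BaselineSpec", "impute_baseline", "impute_with", "lrmc_complete"]

BASELINE_METHODS = ("zero", "mean", "winsorized_mean", "median", "lrmc")


@dataclass
class BaselineSpec:
    """Configuration of one baseline imputer.

    ``winsor_fraction`` is the tail fraction clamped on each side before
    the winsorized mean (must be in [0, 0.5)). LRMC runs an iterative SVD
    reconstruction: hard-truncated at ``lrmc_rank`` when given, otherwise
    soft-thresholded at ``lrmc_shrinkage`` times the largest singular
    value of the initial fill.
    """

    method: str
    winsor_fraction: float = 0.05
    lrmc_rank: int | None = 3
    lrmc_shrinkage: float | None = None
    lrmc_max_iter: int = 500
    lrmc_tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.method not in BASELINE_METHODS:
            raise ValueError(f"unknown baseline {self.method!r}; choose one of {BASELINE_METHODS}")
        if not 0 <= self.winsor_fraction < 0.5:
            raise ValueError("winsor_fraction must lie in [0, 0.5)")


def _column_statistic(obs: np.ndarray, spec: BaselineSpec) -> float:
    if spec.method == "mean":
        return float(np.mean(obs))
    if spec.method == "median":
        return float(np.median(obs))
    # winsorized mean: clamp the winsor_fraction tails, then average
    return float(np.mean(winsorize(obs, limits=(spec.winsor_fraction, spec.winsor_fraction))))


def lrmc_complete(
    values: np.ndarray,
    mask: np.ndarray,
    rank: int | None = 3,
    shrinkage: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> np.ndarray:
    """Iterative low-rank completion of the masked cells.

    Missing cells are initialized at their column means; each iteration
    reconstructs the matrix from a truncated (or soft-thresholded) SVD and
    copies the reconstruction back into the missing cells, until the
    largest change at a missing cell drops below ``tol``. Non-convergence
    returns the last iterate with a warning. Observed cells are never
    altered.
    """
    values = np.asarray(values, float)
    mask = np.asarray(mask, bool)
    if not (~mask).any():
        return values.copy()
    col_means = np.array([
        np.mean(values[mask[:, j], j]) if mask[:, j].any() else np.nan
        for j in range(values.shape[1])
    ])
    if np.isnan(col_means[np.flatnonzero((~mask).any(axis=0))]).any():
        j = int(np.flatnonzero(np.isnan(col_means))[0])
        raise ValueError(f"column {j} is fully missing; cannot initialize completion")
    A = np.where(mask, values, col_means[None, :])
    lam = None
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        if rank is not None:
            s_t = np.where(np.arange(s.size) < rank, s, 0.0)
        else:
            if lam is None:
                lam = (shrinkage if shrinkage is not None else 0.1) * s[0]
            s_t = np.maximum(s - lam, 0.0)
        low = (U * s_t) @ Vt
        delta = np.max(np.abs(low[~mask] - A[~mask]))
        A[~mask] = low[~mask]
        if delta < tol:
            break
    else:
        warnings.warn("low-rank completion did not converge; returning last iterate", stacklevel=2)
    return A


def impute_baseline(m: FeatureMatrix, spec: BaselineSpec) -> FeatureMatrix:
    """Fill every masked cell of ``m`` per the baseline ``spec``.

    Column-statistic methods raise on a column that is fully missing (no
    statistic can be formed); the zero method never does.
    """
    out = m.copy()
    if out.imputed is None:
        out.imputed = np.zeros_like(out.mask)
    missing = ~m.mask
    if not missing.any():
        return out

    if spec.method == "zero":
        out.values[missing] = 0.0
    elif spec.method == "lrmc":
        completed = lrmc_complete(
            m.values, m.mask, spec.lrmc_rank, spec.lrmc_shrinkage, spec.lrmc_max_iter, spec.lrmc_tol
        )
        out.values[missing] = completed[missing]
    else:
        for j in np.flatnonzero(missing.any(axis=0)):
            obs = m.values[m.mask[:, j], j]
            if obs.size == 0:
                raise ValueError(f"column {m.feature_specs[j].name!r} is fully missing")
            out.values[missing[:, j], j] = _column_statistic(obs, spec)
    out.mask[missing] = True
    out.imputed[missing] = True
    return out


def impute_with(m: FeatureMatrix, fill: Callable[[np.ndarray, np.ndarray], np.ndarray]) -> FeatureMatrix:
    """Plug-in slot: ``fill(values, mask)`` returns a completed grid whose
    values at masked cells are copied in; observed cells are preserved."""
    completed = np.asarray(fill(m.values.copy(), m.mask.copy()), float)
    if completed.shape != m.values.shape:
        raise ValueError("external imputer changed the matrix shape")
    out = m.copy()
    if out.imputed is None:
        out.imputed = np.zeros_like(out.mask)
    missing = ~m.mask
    out.values[missing] = completed[missing]
    out.mask[missing] = True
    out.imputed[missing] = True
    return out
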