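"""Neighborhood-weighted imputation of missing clinical test scores.

For a patient x with a missing score cs, the prediction is the
similarity-weighted average of the observed cs values of the BNC (best
neighbor count) most similar patients:

    p(x, cs) = sum_k  s_k * w_k  /  sum_k  w_k,     k = 1..BNC

where w_k are the pairwise weights of one of the five similarity measures
computed over a chosen feature-vector form: only morphometrics, only
demographics (which include the other clinical scores), or the hybrid of
both. The score being predicted never enters its own similarity vector
(leave-one-out integrity), neighbors must have the target score observed,
and values imputed earlier in the same run are never reused as neighbor
scores.

Weights are used signed, exactly as the weighted-average formula is
written; when the weight sum is numerically zero the prediction falls back
to the unweighted neighbor mean (flagged on the record). An alternative
absolute-weight denominator is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import FeatureMatrix
from .similarity import (
    DISTANCE_MEASURES,
    canonical_measure,
    resolve_infinite,
    similarity_matrix,
)

__all__ = [
    "FEATURE_FORMS",
    "Neighbor",
    "NeighborSet",
    "Prediction",
    "ImputationFailure",
    "ImputationResult",
    "feature_form_columns",
    "select_neighbors",
    "predict",
    "impute",
]

FEATURE_FORMS = ("morphometrics", "demographics", "hybrid")

_ZERO_WEIGHT_SUM = 1e-12


@dataclass(frozen=True)
class Neighbor:
    sample_id: object
    weight: float
    score: float


@dataclass
class NeighborSet:
    """Top-BNC candidates for one (target sample, score) cell, sorted by
    weight descending; ties broken by ascending sample id."""

    target_sample: object
    score_type: str
    neighbors: list[Neighbor]
    bnc: int


@dataclass
class Prediction:
    """One imputed cell, in normalized [0, 1] units."""

    target_sample: object
    score_type: str
    value: float
    n_neighbors_used: int
    measure: str
    fallback_mean: bool = False


@dataclass
class ImputationFailure:
    target_sample: object
    score_type: str
    reason: str


@dataclass
class ImputationResult:
    matrix: FeatureMatrix
    predictions: list[Prediction]
    failures: list[ImputationFailure]


def feature_form_columns(m: FeatureMatrix, feature_form: str) -> list[int]:
    """Column indices entering the similarity vector for a feature form.

    Demographics deliberately include the clinical-score columns (the
    scores are themselves demographic attributes of the cohort table); the
    hybrid form is their union with the morphometrics.
    """
    if feature_form not in FEATURE_FORMS:
        raise ValueError(f"unknown feature form {feature_form!r}; choose one of {FEATURE_FORMS}")
    if feature_form == "morphometrics":
        roles = ("morphometric",)
    elif feature_form == "demographics":
        roles = ("demographic", "clinical_score")
    else:
        roles = ("morphometric", "demographic", "clinical_score")
    return [j for j, s in enumerate(m.feature_specs) if s.role in roles]


def _id_rank(sample_ids: Sequence) -> np.ndarray:
    """Rank of each sample id under ascending id order (tie-break key)."""
    order = sorted(range(len(sample_ids)), key=lambda i: str(sample_ids[i]))
    rank = np.empty(len(sample_ids), dtype=np.int64)
    for r, i in enumerate(order):
        rank[i] = r
    return rank


def _sorted_candidates(
    weights_row: np.ndarray,
    candidate_idx: np.ndarray,
    id_rank: np.ndarray,
) -> np.ndarray:
    """Candidate row indices sorted by weight desc, then sample id asc."""
    w = weights_row[candidate_idx]
    ok = np.isfinite(w)
    cand = candidate_idx[ok]
    w = w[ok]
    if cand.size == 0:
        return cand
    order = np.lexsort((id_rank[cand], -w))
    return cand[order]


def select_neighbors(
    m: FeatureMatrix,
    target: object,
    score_type: str,
    weights: np.ndarray,
    bnc: int,
) -> NeighborSet:
    """Pick the top-``bnc`` valid neighbors with ``score_type`` observed.

    ``weights`` is the (resolved) similarity row of the target sample.
    If fewer than ``bnc`` candidates exist, all are returned; zero
    candidates raises.
    """
    if bnc < 1:
        raise ValueError("bnc must be >= 1")
    t = m.sample_ids.index(target)
    cs = m.score_columns()[score_type]
    cand = np.flatnonzero(m.mask[:, cs])
    cand = cand[cand != t]
    chosen = _sorted_candidates(np.asarray(weights, float), cand, _id_rank(m.sample_ids))[:bnc]
    if chosen.size == 0:
        raise ValueError(f"no neighbor candidates for sample {target!r}, score {score_type!r}")
    return NeighborSet(
        target,
        score_type,
        [Neighbor(m.sample_ids[i], float(weights[i]), float(m.values[i, cs])) for i in chosen],
        bnc,
    )


def predict(ns: NeighborSet, measure: str = "man", abs_weights: bool = False) -> Prediction:
    """Weighted average of the neighbor scores by their weights."""
    if not ns.neighbors:
        raise ValueError("empty neighbor set")
    s = np.array([nb.score for nb in ns.neighbors])
    w = np.array([nb.weight for nb in ns.neighbors])
    den = np.sum(np.abs(w)) if abs_weights else np.sum(w)
    if abs(den) < _ZERO_WEIGHT_SUM:
        return Prediction(ns.target_sample, ns.score_type, float(np.mean(s)), len(s), measure,
                          fallback_mean=True)
    return Prediction(ns.target_sample, ns.score_type, float(np.sum(s * w) / den), len(s), measure)


def _candidate_tables(
    m: FeatureMatrix,
    measure: str,
    feature_form: str,
    min_overlap: int = 2,
    infinite_per_row: bool = False,
) -> dict[str, dict]:
    """Per score type: sorted neighbor weights/scores for every missing cell.

    Shared workhorse for :func:`impute` and the evaluation sweep: the
    similarity matrix for a score type is computed once (on the feature
    form minus that score) and each missing cell gets its candidates
    pre-sorted, so predictions for any BNC are cumulative sums.
    """
    measure = canonical_measure(measure)
    form_cols = feature_form_columns(m, feature_form)
    id_rank = _id_rank(m.sample_ids)
    tables: dict[str, dict] = {}
    for score, cs in m.score_columns().items():
        targets = np.flatnonzero(~m.mask[:, cs])
        if targets.size == 0:
            continue
        cols = [j for j in form_cols if j != cs]
        sm = similarity_matrix(m.values[:, cols], measure, min_overlap=min_overlap)
        if measure in DISTANCE_MEASURES and np.isinf(sm.weights).any():
            sm = resolve_infinite(sm, per_row=infinite_per_row)
        observed = np.flatnonzero(m.mask[:, cs])
        per_target = {}
        for t in targets:
            cand = observed[observed != t]
            chosen = _sorted_candidates(sm.weights[t], cand, id_rank)
            per_target[int(t)] = (
                sm.weights[t, chosen].astype(float),
                m.values[chosen, cs].astype(float),
            )
        tables[score] = {"column": cs, "targets": per_target}
    return tables


def _predict_sorted(w: np.ndarray, s: np.ndarray, bnc: int, abs_weights: bool) -> tuple[float, int, bool]:
    k = min(bnc, w.size)
    wk, sk = w[:k], s[:k]
    den = np.sum(np.abs(wk)) if abs_weights else np.sum(wk)
    if abs(den) < _ZERO_WEIGHT_SUM:
        return float(np.mean(sk)), k, True
    return float(np.sum(wk * sk) / den), k, False


def impute(
    m: FeatureMatrix,
    measure: str = "man",
    bnc: int = 6,
    feature_form: str = "hybrid",
    min_overlap: int = 2,
    abs_weights: bool = False,
    infinite_per_row: bool = False,
) -> ImputationResult:
    """Fill every missing clinical-score cell of a preprocessed cohort.

    Non-score missing cells are untouched. Per-cell impossibilities (no
    candidate with the score observed and a valid weight) are recorded as
    failures, never raised. The returned matrix marks filled cells in its
    ``imputed`` grid.
    """
    measure = canonical_measure(measure)
    out = m.copy()
    if out.imputed is None:
        out.imputed = np.zeros_like(out.mask)
    predictions: list[Prediction] = []
    failures: list[ImputationFailure] = []
    tables = _candidate_tables(m, measure, feature_form, min_overlap, infinite_per_row)
    for score, tab in tables.items():
        cs = tab["column"]
        for t, (w, s) in tab["targets"].items():
            if w.size == 0:
                failures.append(
                    ImputationFailure(m.sample_ids[t], score, "no valid neighbor candidates")
                )
                continue
            value, k, fb = _predict_sorted(w, s, bnc, abs_weights)
            predictions.append(
                Prediction(m.sample_ids[t], score, value, k, measure, fallback_mean=fb)
            )
            out.values[t, cs] = value
            out.mask[t, cs] = True
            out.imputed[t, cs] = True
    return ImputationResult(out, predictions, failures)
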