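"""Masking-based benchmarking of imputers.

The protocol: for each clinical test score, empty k originally observed
cells chosen uniformly at random (a :class:`MaskingPlan`), run an imputer
on the masked cohort, and compare the imputed values to the hidden actual
values with MAE, MSE, RMSE and R-squared; repeat with fresh plans and
report per-configuration metrics averaged over repeats. Masked cells are
hidden from the similarity vectors as well as from the prediction targets
(no leakage). Configurations are ordered by the sum of their per-metric
ranks (MAE and RMSE ascending, R-squared descending).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .baselines import BASELINE_METHODS, BaselineSpec, impute_baseline
from .data_model import FeatureMatrix
from .imputer import _candidate_tables, _predict_sorted

__all__ = [
    "MaskingPlan",
    "MetricReport",
    "ComparisonStats",
    "ExperimentConfig",
    "make_plan",
    "apply_plan",
    "metrics",
    "compare",
    "run_experiment",
    "rank_configs",
    "leaderboard",
]


@dataclass
class MaskingPlan:
    """The (sample, score) cells emptied in one evaluation trial."""

    cells: dict[str, list]  # score name -> sample ids to empty
    samples_per_score: int
    seed: int

    @property
    def n_cells(self) -> int:
        return sum(len(v) for v in self.cells.values())


@dataclass
class ExperimentConfig:
    """One imputer configuration entering the benchmark."""

    technique: str  # "ducf" or a baseline method name
    feature_form: str | None = None
    measure: str | None = None
    bnc: int | None = None
    baseline: BaselineSpec | None = None

    @property
    def label(self) -> str:
        if self.technique == "ducf":
            return f"ducf/{self.feature_form}/{self.measure}/bnc={self.bnc}"
        return self.technique


@dataclass
class MetricReport:
    """Imputation quality of one configuration.

    For a single trial (``n_repeats == 1``) ``rmse == sqrt(mse)``
    exactly; reports averaged over repeats carry the mean of the
    per-repeat values of each metric, so that identity holds only
    per trial.
    """

    config: ExperimentConfig | None
    mae: float
    mse: float
    rmse: float
    r_squared: float
    n_cells: int
    n_repeats: int = 1
    r2_valid: bool = True
    n_failed: int = 0


@dataclass
class ComparisonStats:
    """Actual-vs-imputed association and paired-difference statistics."""

    pearson_r: float
    df: int
    t_statistic: float
    p_value: float
    mean_actual: float
    sd_actual: float
    mean_imputed: float
    sd_imputed: float
    t_valid: bool = True


def make_plan(m: FeatureMatrix, k: int, seed: int) -> MaskingPlan:
    """Choose, per clinical score, min(k, observed) originally observed
    samples uniformly without replacement; reproducible from ``seed``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    cells: dict[str, list] = {}
    for score, cs in m.score_columns().items():
        observed = np.flatnonzero(m.mask[:, cs])
        if observed.size == 0:
            warnings.warn(f"score {score!r} has no observed values; excluded from plan", stacklevel=2)
            continue
        take = min(k, observed.size)
        chosen = np.sort(rng.choice(observed, size=take, replace=False))
        cells[score] = [m.sample_ids[i] for i in chosen]
    return MaskingPlan(cells, k, seed)


def apply_plan(m: FeatureMatrix, plan: MaskingPlan) -> tuple[FeatureMatrix, dict[str, np.ndarray]]:
    """Empty the plan's cells; return the masked cohort and the hidden
    actual values per score (in plan order)."""
    out = m.copy()
    actual: dict[str, np.ndarray] = {}
    score_cols = m.score_columns()
    for score, ids in plan.cells.items():
        cs = score_cols[score]
        idx = [m.sample_ids.index(i) for i in ids]
        vals = m.values[idx, cs]
        if np.isnan(vals).any():
            raise ValueError(f"plan masks an unobserved cell for score {score!r}")
        actual[score] = vals.copy()
        out.values[idx, cs] = np.nan
        out.mask[idx, cs] = False
    return out, actual


def metrics(actual: Sequence[float], imputed: Sequence[float],
            config: ExperimentConfig | None = None) -> MetricReport:
    """MAE, MSE, RMSE and R-squared of imputed vs actual values.

    R-squared is one minus the ratio of squared imputation error to the
    squared deviation of the actual values about their own mean; with
    zero-variance actual values it is undefined and flagged invalid.
    """
    x = np.asarray(actual, float)
    y = np.asarray(imputed, float)
    if x.shape != y.shape:
        raise ValueError("actual and imputed must have equal length")
    if x.size == 0:
        raise ValueError("empty value lists")
    err = y - x
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    if x.size < 2 or ss_tot == 0.0:
        return MetricReport(config, mae, mse, rmse, np.nan, x.size, r2_valid=False)
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return MetricReport(config, mae, mse, rmse, r2, x.size)


def compare(actual: Sequence[float], imputed: Sequence[float]) -> ComparisonStats:
    """Pearson correlation and paired t-test between actual and imputed."""
    x = np.asarray(actual, float)
    y = np.asarray(imputed, float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    r = float(stats.pearsonr(x, y).statistic)
    d = x - y
    if np.std(d, ddof=1) == 0.0:
        # identically-zero differences: no difference at all, t = 0;
        # constant nonzero difference: t undefined, flagged
        if np.all(d == 0.0):
            return ComparisonStats(r, x.size - 1, 0.0, 1.0, float(x.mean()),
                                   float(x.std(ddof=1)), float(y.mean()), float(y.std(ddof=1)))
        return ComparisonStats(r, x.size - 1, np.nan, np.nan, float(x.mean()),
                               float(x.std(ddof=1)), float(y.mean()), float(y.std(ddof=1)),
                               t_valid=False)
    t = stats.ttest_rel(x, y)
    return ComparisonStats(
        r, x.size - 1, float(t.statistic), float(t.pvalue),
        float(x.mean()), float(x.std(ddof=1)), float(y.mean()), float(y.std(ddof=1)),
    )


def _ducf_trial_predictions(
    masked: FeatureMatrix,
    plan: MaskingPlan,
    feature_form: str,
    measure: str,
    bncs: Sequence[int],
    min_overlap: int,
) -> dict[int, tuple[list[float], int]]:
    """Predictions at the plan cells for every BNC in one pass.

    Candidates are pre-sorted per cell, so each BNC is a truncated
    weighted average of the same sorted lists. Returns, per BNC, the
    prediction list aligned with the plan's cell order (NaN where a cell
    failed) and the failure count.
    """
    tables = _candidate_tables(masked, measure, feature_form, min_overlap)
    row_of = {sid: i for i, sid in enumerate(masked.sample_ids)}
    out: dict[int, tuple[list[float], int]] = {b: ([], 0) for b in bncs}
    preds: dict[int, list[float]] = {b: [] for b in bncs}
    fails: dict[int, int] = {b: 0 for b in bncs}
    for score, ids in plan.cells.items():
        per_target = tables.get(score, {}).get("targets", {})
        for sid in ids:
            t = row_of[sid]
            w_s = per_target.get(t)
            for b in bncs:
                if w_s is None or w_s[0].size == 0:
                    preds[b].append(np.nan)
                    fails[b] += 1
                else:
                    value, _, _ = _predict_sorted(w_s[0], w_s[1], b, False)
                    preds[b].append(value)
    return {b: (preds[b], fails[b]) for b in bncs}


def run_experiment(
    m: FeatureMatrix,
    configs: Sequence[ExperimentConfig],
    k: int,
    n_repeats: int,
    base_seed: int,
    min_overlap: int = 2,
) -> list[MetricReport]:
    """Run the full masking protocol for every configuration.

    Per repeat a fresh plan (seed ``base_seed + repeat``) empties k cells
    per score; each configuration imputes the same masked cohort; metrics
    are computed per repeat and averaged. Cells no configuration could
    impute are excluded from that configuration's metrics, with failure
    counts accumulated on the report.
    """
    acc: dict[int, list[MetricReport]] = {i: [] for i in range(len(configs))}
    ducf_groups: dict[tuple[str, str], list[int]] = {}
    for i, cfg in enumerate(configs):
        if cfg.technique == "ducf":
            ducf_groups.setdefault((cfg.feature_form, cfg.measure), []).append(i)
        elif cfg.technique not in BASELINE_METHODS:
            raise ValueError(f"unknown technique {cfg.technique!r}")

    for rep in range(n_repeats):
        plan = make_plan(m, k, base_seed + rep)
        masked, actual = apply_plan(m, plan)
        flat_actual = np.concatenate([actual[s] for s in plan.cells]) if plan.cells else np.array([])

        for (form, measure), idxs in ducf_groups.items():
            bncs = sorted({configs[i].bnc for i in idxs})
            by_bnc = _ducf_trial_predictions(masked, plan, form, measure, bncs, min_overlap)
            for i in idxs:
                preds, n_failed = by_bnc[configs[i].bnc]
                preds = np.asarray(preds)
                ok = np.isfinite(preds)
                rep_metrics = metrics(flat_actual[ok], preds[ok], configs[i])
                rep_metrics.n_failed = n_failed
                acc[i].append(rep_metrics)

        for i, cfg in enumerate(configs):
            if cfg.technique == "ducf":
                continue
            spec = cfg.baseline or BaselineSpec(cfg.technique)
            filled = impute_baseline(masked, spec)
            score_cols = m.score_columns()
            preds = np.concatenate([
                filled.values[[m.sample_ids.index(s) for s in ids], score_cols[score]]
                for score, ids in plan.cells.items()
            ])
            acc[i].append(metrics(flat_actual, preds, cfg))

    reports: list[MetricReport] = []
    for i, cfg in enumerate(configs):
        reps = acc[i]
        r2s = np.array([r.r_squared for r in reps])
        r2_valid = all(r.r2_valid for r in reps)
        reports.append(
            MetricReport(
                cfg,
                mae=float(np.mean([r.mae for r in reps])),
                mse=float(np.mean([r.mse for r in reps])),
                rmse=float(np.mean([r.rmse for r in reps])),
                r_squared=float(np.nanmean(r2s)) if np.isfinite(r2s).any() else np.nan,
                n_cells=int(sum(r.n_cells for r in reps)),
                n_repeats=n_repeats,
                r2_valid=r2_valid,
                n_failed=int(sum(r.n_failed for r in reps)),
            )
        )
    return reports


_RANK_METRICS = ("mae", "rmse", "r_squared")


def rank_configs(
    reports: Sequence[MetricReport],
    metrics_used: Sequence[str] = _RANK_METRICS,
) -> list[MetricReport]:
    """Order configurations by the sum of their per-metric ranks.

    Within each metric, ranks 1..K are assigned (average rank on ties);
    MAE and RMSE rank ascending, R-squared descending. An invalid metric
    value ranks last for that metric, with a warning. Ties in rank sum are
    broken by MAE, then input order (stable).
    """
    if len(reports) < 2:
        return list(reports)
    ranksum = np.zeros(len(reports))
    for name in metrics_used:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        if name == "r_squared":
            vals = -vals
        bad = ~np.isfinite(vals)
        if bad.any():
            warnings.warn(f"invalid {name} in {int(bad.sum())} report(s); ranked last", stacklevel=2)
            vals = np.where(bad, np.inf, vals)
            vals[bad] = np.inf
        ranksum += stats.rankdata(vals, method="average")
    order = sorted(range(len(reports)), key=lambda i: (ranksum[i], reports[i].mae, i))
    return [reports[i] for i in order]


def leaderboard(reports: Sequence[MetricReport]):
    """Rank-ordered results as a DataFrame (technique, feature set,
    measure, BNC, MAE, RMSE, R-squared)."""
    import pandas as pd

    ordered = rank_configs(reports)
    rows = []
    for r in ordered:
        cfg = r.config
        rows.append({
            "technique": cfg.technique if cfg else "?",
            "feature_set": (cfg.feature_form or "-") if cfg else "-",
            "measure": (cfg.measure or "-") if cfg else "-",
            "bnc": (cfg.bnc if cfg and cfg.bnc is not None else "-"),
            "mae": r.mae,
            "rmse": r.rmse,
            "r_squared": r.r_squared,
        })
    return pd.DataFrame(rows)
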