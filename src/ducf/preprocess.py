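"""Cohort preprocessing: anomaly filtering, hemisphere averaging,
keyword-based morphometric selection, and functional [0, 1] normalization.

The pipeline mirrors how FreeSurfer-derived tables are conventionally
prepared: regional volumes are expressed as fractions of total
intracranial volume, gray-matter volumes as fractions of total gray
volume, everything else (except nominal codes) is min-max scaled, and
clinical scores are scaled on their observed instrument range so that all
tests share one [0, 1] scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .data_model import KEYWORD_CLASSES, FeatureMatrix, FeatureSpec, _detect_hemisphere

__all__ = [
    "NormalizationPlan",
    "build_normalization_plan",
    "average_hemispheres",
    "select_morphometrics",
    "normalize",
    "filter_anomalies",
    "preprocess_pipeline",
    "DEFAULT_ICV_NAME",
    "DEFAULT_GRAYTOTAL_NAME",
]

DEFAULT_ICV_NAME = "EstimatedTotalIntraCranialVol"
DEFAULT_GRAYTOTAL_NAME = "TotalGrayVol"


@dataclass
class NormalizationPlan:
    """Per-feature normalization rules.

    ``rules`` maps a feature name to one of ``("none", None)``,
    ``("min_max", None)`` or ``("divide_by_reference", reference_name)``.
    Reference-divided features are additionally min-max rescaled after the
    division so every non-nominal feature ends up in [0, 1].
    """

    rules: dict[str, tuple[str, str | None]]
    icv_name: str = DEFAULT_ICV_NAME
    graytotal_name: str = DEFAULT_GRAYTOTAL_NAME


def build_normalization_plan(
    m: FeatureMatrix,
    icv_name: str = DEFAULT_ICV_NAME,
    graytotal_name: str = DEFAULT_GRAYTOTAL_NAME,
) -> NormalizationPlan:
    """Derive the standard plan from feature roles and keyword classes.

    volumemm3 features are divided by intracranial volume, grayvol
    features by total gray volume, nominal features are left alone, and
    everything else (clinical scores included) is min-max scaled.
    """
    names = set(m.feature_names)
    rules: dict[str, tuple[str, str | None]] = {}
    for spec in m.feature_specs:
        if spec.nominal:
            rules[spec.name] = ("none", None)
        elif spec.name in (icv_name, graytotal_name):
            rules[spec.name] = ("min_max", None)
        elif spec.keyword_class == "volumemm3" and icv_name in names:
            rules[spec.name] = ("divide_by_reference", icv_name)
        elif spec.keyword_class == "grayvol" and graytotal_name in names:
            rules[spec.name] = ("divide_by_reference", graytotal_name)
        else:
            rules[spec.name] = ("min_max", None)
    return NormalizationPlan(rules, icv_name, graytotal_name)


def average_hemispheres(m: FeatureMatrix) -> FeatureMatrix:
    """Average left/right morphometric pairs into single bilateral features.

    Pairs are identified by identical base names after stripping the
    hemisphere prefix. The bilateral value is the arithmetic mean of the
    two sides; if one side is missing for a sample the observed side is
    used and the cell stays observed. Unpaired features pass through
    unchanged, preserving order (a pair takes the position of its first
    member).
    """
    specs = m.feature_specs
    base_of: list[str | None] = []
    for spec in specs:
        if spec.role == "morphometric" and spec.hemisphere in ("left", "right"):
            _, base = _detect_hemisphere(spec.name)
            base_of.append(base)
        else:
            base_of.append(None)

    existing = set(m.feature_names)
    sides: dict[str, dict[str, int]] = {}
    for j, base in enumerate(base_of):
        if base is None:
            continue
        sides.setdefault(base, {})[specs[j].hemisphere] = j

    new_cols: list[np.ndarray] = []
    new_mask: list[np.ndarray] = []
    new_specs: list[FeatureSpec] = []
    consumed: set[int] = set()
    for j, spec in enumerate(specs):
        if j in consumed:
            continue
        base = base_of[j]
        if base is not None and len(sides[base]) == 2:
            jl, jr = sides[base]["left"], sides[base]["right"]
            if base in existing and base not in (specs[jl].name, specs[jr].name):
                raise ValueError(
                    f"hemisphere averaging of {specs[jl].name!r}/{specs[jr].name!r} "
                    f"collides with existing feature {base!r}"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col = np.nanmean(m.values[:, [jl, jr]], axis=1)
            msk = m.mask[:, jl] | m.mask[:, jr]
            new_cols.append(np.where(msk, col, np.nan))
            new_mask.append(msk)
            new_specs.append(replace(spec, name=base, hemisphere="bilateral"))
            consumed.update((jl, jr))
        else:
            new_cols.append(m.values[:, j])
            new_mask.append(m.mask[:, j])
            new_specs.append(spec)
    return FeatureMatrix(
        np.column_stack(new_cols), np.column_stack(new_mask), list(m.sample_ids), new_specs
    )


def select_morphometrics(m: FeatureMatrix, keywords: Iterable[str]) -> FeatureMatrix:
    """Keep morphometrics whose keyword class is in ``keywords``, plus all
    demographic and clinical-score columns, preserving column order."""
    keywords = set(keywords)
    unknown = keywords - set(KEYWORD_CLASSES)
    if unknown:
        raise ValueError(f"unknown keyword classes: {sorted(unknown)}")
    keep = [
        j
        for j, s in enumerate(m.feature_specs)
        if s.role != "morphometric" or s.keyword_class in keywords
    ]
    if not keep:
        raise ValueError("no features selected")
    return FeatureMatrix(
        m.values[:, keep],
        m.mask[:, keep],
        list(m.sample_ids),
        [m.feature_specs[j] for j in keep],
    )


def normalize(m: FeatureMatrix, plan: NormalizationPlan | None = None) -> FeatureMatrix:
    """Functionally normalize every non-nominal feature to [0, 1].

    ``divide_by_reference`` features are divided per sample by the
    reference column, then min-max rescaled over observed entries.
    ``min_max`` features are rescaled over observed entries. Clinical
    scores are rescaled on their schema's observed range so all tests share
    one scale. Nominal features and masks are untouched. A constant column
    is set to 0 for all observed samples with a warning; a non-positive or
    missing reference value raises.
    """
    if plan is None:
        plan = build_normalization_plan(m)
    values = m.values.copy()
    for j, spec in enumerate(m.feature_specs):
        col = values[:, j]
        obs = m.mask[:, j]
        if not obs.any():
            continue
        if spec.role == "clinical_score":
            lo, hi = spec.score_schema.observed_range
            values[:, j] = np.where(obs, (col - lo) / (hi - lo), np.nan)
            continue
        rule, ref_name = plan.rules.get(spec.name, ("min_max", None))
        if rule == "none":
            continue
        if rule == "divide_by_reference":
            ref = m.values[:, m.column_index(ref_name)]
            need = obs
            if np.any(need & ~np.isfinite(ref)):
                raise ValueError(f"reference {ref_name!r} missing for samples needing it ({spec.name!r})")
            if np.any(need & (ref <= 0)):
                raise ValueError(f"reference {ref_name!r} has non-positive values")
            col = np.where(need, col / ref, np.nan)
        lo = np.nanmin(col)
        hi = np.nanmax(col)
        if hi - lo <= 0:
            warnings.warn(
                f"feature {spec.name!r} is constant; set to 0 for all samples", stacklevel=2
            )
            values[:, j] = np.where(obs, 0.0, np.nan)
        else:
            values[:, j] = np.where(obs, (col - lo) / (hi - lo), np.nan)
    return FeatureMatrix(values, m.mask.copy(), list(m.sample_ids), list(m.feature_specs),
                         None if m.imputed is None else m.imputed.copy())


def filter_anomalies(
    m: FeatureMatrix,
    row_missing_frac: float = 0.5,
    col_missing_frac: float = 0.2,
    zero_variance: bool = True,
) -> tuple[FeatureMatrix, dict]:
    """Drop anomalous morphometric columns and samples.

    A morphometric column is dropped when its missing fraction exceeds
    ``col_missing_frac`` or (optionally) when it has zero variance over
    observed entries; a sample row is dropped when its missing fraction
    among the surviving morphometrics exceeds ``row_missing_frac``.
    Returns the filtered matrix and a report of dropped names/ids.
    """
    if not (0 <= row_missing_frac <= 1 and 0 <= col_missing_frac <= 1):
        raise ValueError("missing fractions must lie in [0, 1]")
    morpho = [j for j, s in enumerate(m.feature_specs) if s.role == "morphometric"]
    dropped_cols: list[str] = []
    keep_cols: list[int] = []
    for j in range(m.n_features):
        if j not in morpho:
            keep_cols.append(j)
            continue
        col_missing = 1.0 - m.mask[:, j].mean()
        reason = None
        if col_missing > col_missing_frac:
            reason = "missing"
        elif zero_variance and m.mask[:, j].any():
            obs = m.values[m.mask[:, j], j]
            if obs.size and np.nanmax(obs) == np.nanmin(obs):
                reason = "zero_variance"
        if reason is None:
            keep_cols.append(j)
        else:
            dropped_cols.append(m.feature_specs[j].name)

    surviving_morpho = [j for j in keep_cols if j in set(morpho)]
    if surviving_morpho:
        row_missing = 1.0 - m.mask[:, surviving_morpho].mean(axis=1)
    else:
        row_missing = np.zeros(m.n_samples)
    keep_rows = np.flatnonzero(row_missing <= row_missing_frac)
    dropped_rows = [m.sample_ids[i] for i in np.flatnonzero(row_missing > row_missing_frac)]
    if keep_rows.size == 0:
        raise ValueError("all samples dropped by anomaly filtering")

    out = FeatureMatrix(
        m.values[np.ix_(keep_rows, keep_cols)],
        m.mask[np.ix_(keep_rows, keep_cols)],
        [m.sample_ids[i] for i in keep_rows],
        [m.feature_specs[j] for j in keep_cols],
    )
    report = {"dropped_columns": dropped_cols, "dropped_rows": dropped_rows}
    return out, report


def preprocess_pipeline(
    m: FeatureMatrix,
    keywords: Iterable[str] = KEYWORD_CLASSES,
    row_missing_frac: float = 0.5,
    col_missing_frac: float = 0.2,
    zero_variance: bool = True,
    icv_name: str = DEFAULT_ICV_NAME,
    graytotal_name: str = DEFAULT_GRAYTOTAL_NAME,
    drop_references: bool = True,
) -> FeatureMatrix:
    """Anomaly filtering -> hemisphere averaging -> keyword selection ->
    normalization, in that order.

    The reference volumes are denominators, not predictors: with
    ``drop_references`` they are removed from the output feature set after
    normalization.
    """
    m, _ = filter_anomalies(m, row_missing_frac, col_missing_frac, zero_variance)
    m = average_hemispheres(m)
    m = select_morphometrics(m, keywords)
    plan = build_normalization_plan(m, icv_name, graytotal_name)
    m = normalize(m, plan)
    if drop_references:
        names = set(m.feature_names)
        refs = [r for r in (icv_name, graytotal_name) if r in names]
        if refs:
            keep = [j for j, s in enumerate(m.feature_specs) if s.name not in refs]
            m = FeatureMatrix(
                m.values[:, keep], m.mask[:, keep], list(m.sample_ids),
                [m.feature_specs[j] for j in keep],
            )
    return m
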