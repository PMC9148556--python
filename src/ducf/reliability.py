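"""Reliability scale for clinical test scores.

A clinical test score is checked against a computer-aided prediction of
the same score. The discrepancy is reported two ways:

* the **absolute error percentage**, 100 * |score - prediction| / R, where
  R is the width of the instrument's full range (30 for MMSE on [0, 30],
  4 for CDR on [-1, 3], ...);
* a three-tier verdict against per-test thresholds on the raw point
  difference d = |score - prediction|: ``trusted`` when d <= trusted
  threshold, ``moderate`` when it lies between the two thresholds, and
  ``not_trusted`` beyond the moderate threshold — a flag that the clinical
  test should be repeated.

Thresholds are fitted from an imputation-error sample by the two-sigma
rule: trusted = 2 * sd(errors) covers about 95% of Gaussian errors. The
moderate bound uses a larger multiplier (default 2.724, i.e. 1.362x the
trusted bound, the ratio observed across published per-test thresholds).
:data:`REFERENCE_THRESHOLDS` ships the published values fitted on an
ADNI-1 screening cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import DEFAULT_SCORE_SCHEMAS, ScoreSchema

__all__ = [
    "ReliabilityThresholds",
    "ReliabilityVerdict",
    "REFERENCE_THRESHOLDS",
    "error_percentage",
    "fit_thresholds",
    "classify",
    "report",
]

LABELS = ("trusted", "moderate", "not_trusted")


@dataclass(frozen=True)
class ReliabilityThresholds:
    """Trusted/moderate bounds on |score - prediction| for one test, in
    raw (denormalized) test points."""

    score_type: str
    trusted: float
    moderate: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.trusted < self.moderate:
            raise ValueError(
                f"{self.score_type}: thresholds must satisfy 0 < trusted < moderate "
                f"(got {self.trusted}, {self.moderate})"
            )


#: Published per-test thresholds, fitted on an ADNI-1 screening cohort's
#: imputation errors; useful as defaults when no local error sample exists.
REFERENCE_THRESHOLDS: dict[str, ReliabilityThresholds] = {
    "MMSE": ReliabilityThresholds("MMSE", 2.162, 2.945, "published ADNI-1 screening reference"),
    "GDS": ReliabilityThresholds("GDS", 1.179, 1.606, "published ADNI-1 screening reference"),
    "CDR": ReliabilityThresholds("CDR", 0.393, 0.535, "published ADNI-1 screening reference"),
    "NIQ": ReliabilityThresholds("NIQ", 2.850, 3.882, "published ADNI-1 screening reference"),
    "FAQ": ReliabilityThresholds("FAQ", 2.948, 4.016, "published ADNI-1 screening reference"),
}


@dataclass(frozen=True)
class ReliabilityVerdict:
    score_type: str
    clinical_value: float
    predicted_value: float
    abs_error_pct: float
    label: str


def error_percentage(score: float, prediction: float, range_r: float) -> float:
    """Absolute error percentage: 100 * |score - prediction| / range,
    reported to two decimals."""
    if range_r <= 0:
        raise ValueError("range must be positive")
    return round(100.0 * abs(score - prediction) / range_r, 2)


def fit_thresholds(
    errors: Mapping[str, Sequence[float]],
    sigma_multiplier_trusted: float = 2.0,
    sigma_multiplier_moderate: float = 2.724,
    population_sd: bool = False,
    min_errors: int = 10,
) -> dict[str, ReliabilityThresholds]:
    """Two-sigma threshold fit from per-test (actual - predicted) error
    samples in raw test points.

    trusted = trusted multiplier x sd(errors) and likewise for moderate;
    the sample standard deviation (n-1) is the default. Raises on fewer
    than ``min_errors`` errors or a degenerate (all-equal) error sample.
    """
    if not 0 < sigma_multiplier_trusted < sigma_multiplier_moderate:
        raise ValueError("need 0 < trusted multiplier < moderate multiplier")
    out: dict[str, ReliabilityThresholds] = {}
    for score_type, errs in errors.items():
        e = np.asarray(errs, float)
        if e.size < min_errors:
            raise ValueError(f"{score_type}: need at least {min_errors} errors, got {e.size}")
        sd = float(np.std(e, ddof=0 if population_sd else 1))
        if sd == 0.0:
            raise ValueError(f"{score_type}: degenerate errors (zero spread)")
        out[score_type] = ReliabilityThresholds(
            score_type,
            sigma_multiplier_trusted * sd,
            sigma_multiplier_moderate * sd,
            provenance=(
                f"n={e.size}, sd={sd:.6g} ({'population' if population_sd else 'sample'}), "
                f"multipliers=({sigma_multiplier_trusted}, {sigma_multiplier_moderate})"
            ),
        )
    return out


def classify(
    score: float,
    prediction: float,
    thresholds: Mapping[str, ReliabilityThresholds],
    score_type: str,
    schemas: Mapping[str, ScoreSchema] | None = None,
) -> ReliabilityVerdict:
    """Three-tier verdict on one (score, prediction) pair."""
    if score_type not in thresholds:
        raise KeyError(f"no thresholds fitted for score type {score_type!r}")
    schemas = DEFAULT_SCORE_SCHEMAS if schemas is None else schemas
    if score_type not in schemas:
        raise KeyError(f"unknown score type {score_type!r}")
    th = thresholds[score_type]
    d = abs(score - prediction)
    if d <= th.trusted:
        label = "trusted"
    elif d <= th.moderate:
        label = "moderate"
    else:
        label = "not_trusted"
    pct = error_percentage(score, prediction, schemas[score_type].instrument_width)
    return ReliabilityVerdict(score_type, float(score), float(prediction), pct, label)


def report(
    verdicts: Sequence[ReliabilityVerdict],
    schemas: Mapping[str, ScoreSchema] | None = None,
) -> pd.DataFrame:
    """Verdicts as a table: test type, range, clinical score, prediction,
    absolute error percentage, reliability."""
    schemas = DEFAULT_SCORE_SCHEMAS if schemas is None else schemas
    rows = []
    for v in verdicts:
        lo, hi = schemas[v.score_type].instrument_range
        rows.append({
            "Clinical test type": v.score_type,
            "Range": f"[{lo:g}, {hi:g}]",
            "Clinical test score": v.clinical_value,
            "Computer-aided prediction": v.predicted_value,
            "Absolute error percentage": v.abs_error_pct,
            "Reliability": v.label.replace("_", " "),
        })
    columns = [
        "Clinical test type", "Range", "Clinical test score",
        "Computer-aided prediction", "Absolute error percentage", "Reliability",
    ]
    return pd.DataFrame(rows, columns=columns)
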