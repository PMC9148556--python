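"""Core tabular types shared by every stage of the pipeline.

A cohort is held as a :class:`FeatureMatrix`: a dense samples x features
float grid plus an explicit boolean observation mask (``True`` = observed)
and one :class:`FeatureSpec` per column describing the column's role
(morphometric / demographic / clinical score), its FreeSurfer-stats keyword
class, hemisphere, and — for clinical scores — a :class:`ScoreSchema` with
the instrument and observed score ranges.

Cells with ``mask == False`` hold ``NaN`` in ``values`` and are excluded
from every similarity and metric computation downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KEYWORD_CLASSES",
    "ROLES",
    "HEMISPHERES",
    "DEFAULT_SCORE_SCHEMAS",
    "ScoreSchema",
    "FeatureSpec",
    "FeatureMatrix",
    "TableParseError",
    "read_feature_table",
    "write_feature_table",
    "load_config",
    "infer_feature_spec",
]

#: FreeSurfer-stats keyword classes used to tag morphometric columns.
KEYWORD_CLASSES = (
    "general",
    "volumemm3",
    "area",
    "thickavg",
    "grayvol",
    "nvoxels",
    "numvert",
    "nvertices",
)

ROLES = ("morphometric", "demographic", "clinical_score")
HEMISPHERES = ("left", "right", "bilateral", "n/a")

#: Global reference volumes used as normalization denominators.
REFERENCE_FEATURE_HINTS = ("estimatedtotalintracranialvol", "totalgrayvol")

#: Demographic column names recognised by default (case-insensitive).
DEMOGRAPHIC_HINTS = ("sex", "gender", "age", "apoe")
NOMINAL_HINTS = ("sex", "gender", "apoe")

#: Missing-value markers accepted on ingestion (spreadsheet-export tolerant).
MISSING_MARKERS = ("", "NA", "NaN")


class TableParseError(ValueError):
    """Raised when a delimited feature table cannot be parsed."""


@dataclass(frozen=True)
class ScoreSchema:
    """Ranges of one clinical test.

    ``instrument_range`` is the full range of the published instrument
    (e.g. [0, 30] for MMSE) and is the denominator of the absolute error
    percentage; ``observed_range`` is the range actually spanned by the
    cohort (e.g. [8, 30] for MMSE at screening) and is the scale used for
    [0, 1] normalization. The observed range need not be contained in the
    instrument range.
    """

    name: str
    instrument_range: tuple[float, float]
    observed_range: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.instrument_range
        if not lo < hi:
            raise ValueError(f"instrument_range must satisfy min < max, got {self.instrument_range}")
        olo, ohi = self.observed_range
        if not olo < ohi:
            raise ValueError(f"observed_range must satisfy min < max, got {self.observed_range}")

    @property
    def instrument_width(self) -> float:
        lo, hi = self.instrument_range
        return hi - lo

    @property
    def observed_width(self) -> float:
        lo, hi = self.observed_range
        return hi - lo


#: The five clinical tests, with instrument ranges and the observed
#: screening-cohort ranges they are normalized on.
DEFAULT_SCORE_SCHEMAS: dict[str, ScoreSchema] = {
    "MMSE": ScoreSchema("MMSE", (0.0, 30.0), (8.0, 30.0)),
    "GDS": ScoreSchema("GDS", (0.0, 12.0), (0.0, 12.0)),
    "CDR": ScoreSchema("CDR", (-1.0, 3.0), (-1.0, 3.0)),
    "NIQ": ScoreSchema("NIQ", (0.0, 29.0), (0.0, 29.0)),
    "FAQ": ScoreSchema("FAQ", (0.0, 30.0), (0.0, 30.0)),
}


@dataclass(frozen=True)
class FeatureSpec:
    """Per-column metadata: role, keyword class, hemisphere, score schema."""

    name: str
    role: str
    keyword_class: str = "none"
    nominal: bool = False
    hemisphere: str = "n/a"
    score_schema: ScoreSchema | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for feature {self.name!r}")
        if self.keyword_class != "none" and self.keyword_class not in KEYWORD_CLASSES:
            raise ValueError(f"unknown keyword class {self.keyword_class!r} for {self.name!r}")
        if self.keyword_class != "none" and self.role != "morphometric":
            raise ValueError(
                f"feature {self.name!r}: keyword_class={self.keyword_class!r} requires role=morphometric"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {self.hemisphere!r} for {self.name!r}")
        if self.role == "clinical_score" and self.score_schema is None:
            raise ValueError(f"clinical score {self.name!r} needs a ScoreSchema")


_HEMI_RE = re.compile(r"^(left|right|lh|rh)[-_.]", re.IGNORECASE)


def _detect_hemisphere(name: str) -> tuple[str, str]:
    """Return (hemisphere, base name without the hemisphere prefix)."""
    m = _HEMI_RE.match(name)
    if m is None:
        return "bilateral", name
    side = m.group(1).lower()
    hemi = "left" if side in ("left", "lh") else "right"
    return hemi, name[m.end():]


def _detect_keyword(name: str) -> str:
    low = name.lower()
    for hint in REFERENCE_FEATURE_HINTS:
        if hint in low:
            return "general"
    for kw in KEYWORD_CLASSES:
        if kw in low:
            return kw
    return "none"


def infer_feature_spec(
    name: str,
    schemas: Mapping[str, ScoreSchema] | None = None,
) -> FeatureSpec:
    """Infer a :class:`FeatureSpec` from a column name.

    Clinical-score names are matched case-insensitively against ``schemas``
    (defaults to the five standard tests); ``sex``/``age``/``apoE*`` columns
    become demographics; everything else is a morphometric whose keyword
    class and hemisphere follow FreeSurfer naming conventions
    (``Left-``/``Right-``/``lh_``/``rh_`` prefixes, keyword substrings).
    """
    schemas = DEFAULT_SCORE_SCHEMAS if schemas is None else schemas
    for score, schema in schemas.items():
        if name.lower() == score.lower():
            return FeatureSpec(name, "clinical_score", score_schema=schema)
    low = name.lower()
    for hint in DEMOGRAPHIC_HINTS:
        if low.startswith(hint):
            nominal = any(low.startswith(h) for h in NOMINAL_HINTS)
            return FeatureSpec(name, "demographic", nominal=nominal)
    hemi, _ = _detect_hemisphere(name)
    return FeatureSpec(name, "morphometric", keyword_class=_detect_keyword(name), hemisphere=hemi)


@dataclass
class FeatureMatrix:
    """Samples x features grid with an observation mask and per-column specs.

    Invariants: ``values`` and ``mask`` share one shape; masked cells hold
    NaN; ``len(sample_ids) == n_samples`` and ``len(feature_specs) ==
    n_features``. ``imputed`` (same shape, optional) marks cells filled by
    an imputer, for provenance.
    """

    values: np.ndarray
    mask: np.ndarray
    sample_ids: list
    feature_specs: list[FeatureSpec]
    imputed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError(f"values shape {self.values.shape} != mask shape {self.mask.shape}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        if len(self.feature_specs) != self.values.shape[1]:
            raise ValueError("feature_specs length does not match number of columns")
        if len(set(map(str, self.sample_ids))) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        # keep the NaN <-> masked correspondence tight
        self.values = np.where(self.mask, self.values, np.nan)

    # -- introspection -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    def column_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def columns_with_role(self, role: str) -> list[int]:
        return [j for j, s in enumerate(self.feature_specs) if s.role == role]

    def score_columns(self) -> dict[str, int]:
        """Mapping clinical-score name -> column index."""
        return {
            s.name: j for j, s in enumerate(self.feature_specs) if s.role == "clinical_score"
        }

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(),
            self.mask.copy(),
            list(self.sample_ids),
            list(self.feature_specs),
            None if self.imputed is None else self.imputed.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Values as a DataFrame (NaN at masked cells), indexed by sample id."""
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)


# ----------------------------------------------------------------------
# ingestion / serialisation
# ----------------------------------------------------------------------

_ID_COLUMN_HINTS = ("sample_id", "subject_id", "id", "rid")


def read_feature_table(
    path: str | Path,
    schemas: Mapping[str, ScoreSchema] | None = None,
    role_map: Mapping[str, FeatureSpec] | None = None,
    delimiter: str | None = None,
    id_column: str | None = None,
) -> FeatureMatrix:
    """Read a delimited samples x features table into a :class:`FeatureMatrix`.

    Empty cells and the markers ``NA``/``NaN`` map to ``mask = False``.
    Column roles come from ``role_map`` when given, else from name
    inference (:func:`infer_feature_spec`). Sample ids are taken from a
    designated id column (``sample_id``/``subject_id``/``id``/``rid``,
    case-insensitive, or ``id_column``) when present, else the 0-based row
    index.

    Raises :class:`TableParseError` on an empty table, a duplicate sample
    id, or a non-numeric cell (naming its row and column).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        dtype=str,
        na_values=list(MISSING_MARKERS),
        keep_default_na=False,
        skipinitialspace=True,
    )
    if df.shape[0] == 0:
        raise TableParseError(f"{path}: empty table")

    # sample ids
    id_col = None
    if id_column is not None:
        if id_column not in df.columns:
            raise TableParseError(f"{path}: id column {id_column!r} not found")
        id_col = id_column
    else:
        for c in df.columns:
            if c.lower() in _ID_COLUMN_HINTS:
                id_col = c
                break
    if id_col is not None:
        sample_ids = df[id_col].tolist()
        df = df.drop(columns=[id_col])
    else:
        sample_ids = list(range(df.shape[0]))
    if len(set(map(str, sample_ids))) != len(sample_ids):
        raise TableParseError(f"{path}: duplicate sample id")

    n, p = df.shape
    values = np.full((n, p), np.nan)
    for j, col in enumerate(df.columns):
        raw = df[col]
        present = raw.notna().to_numpy()
        # python float() parsing: exact round trip of repr-formatted values
        for i in np.flatnonzero(present):
            cell = raw.iloc[int(i)]
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at row {int(i)}, column {col!r}"
                ) from None
    mask = ~np.isnan(values)

    specs: list[FeatureSpec] = []
    for col in df.columns:
        if role_map is not None and col in role_map:
            specs.append(role_map[col])
        else:
            specs.append(infer_feature_spec(col, schemas))
    return FeatureMatrix(values, mask, sample_ids, specs)


def write_feature_table(m: FeatureMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a :class:`FeatureMatrix` to CSV/TSV; masked cells become empty.

    Values are written with full float precision so that a write/read
    round trip reproduces values, mask and inferred roles exactly.
    """
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(["sample_id", *m.feature_names]) + "\n")
        for i, sid in enumerate(m.sample_ids):
            cells = [str(sid)]
            for j in range(m.n_features):
                # repr is the shortest float64 round-trip representation
                cells.append(repr(float(m.values[i, j])) if m.mask[i, j] else "")
            fh.write(delimiter.join(cells) + "\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config declaring score schemas and role overrides.

    Recognised keys::

        scores:
          MMSE: {instrument: [0, 30], observed: [8, 30]}
        roles:
          SomeColumn: {role: demographic, nominal: true}

    Returns ``{"schemas": {...}, "role_map": {...}}`` suitable for
    :func:`read_feature_table`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schemas = dict(DEFAULT_SCORE_SCHEMAS)
    for name, entry in (raw.get("scores") or {}).items():
        inst = tuple(entry.get("instrument", DEFAULT_SCORE_SCHEMAS[name].instrument_range if name in DEFAULT_SCORE_SCHEMAS else (0, 1)))
        obs = tuple(entry.get("observed", inst))
        schemas[name] = ScoreSchema(name, (float(inst[0]), float(inst[1])), (float(obs[0]), float(obs[1])))
    role_map: dict[str, FeatureSpec] = {}
    for name, entry in (raw.get("roles") or {}).items():
        role = entry.get("role", "morphometric")
        schema = schemas.get(name) if role == "clinical_score" else None
        role_map[name] = FeatureSpec(
            name,
            role,
            keyword_class=entry.get("keyword_class", "none"),
            nominal=bool(entry.get("nominal", False)),
            hemisphere=entry.get("hemisphere", "n/a" if role != "morphometric" else "bilateral"),
            score_schema=schema,
        )
    return {"schemas": schemas, "role_map": role_map}
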