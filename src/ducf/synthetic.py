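"""Synthetic cohorts with the neighborhood structure the imputer assumes.

The generative model is cluster-based: each sample belongs to one of a few
latent severity groups, morphometrics scatter around per-group centroids,
and each clinical test score is a deterministic group-level value plus
Gaussian measurement noise — so similar brains genuinely carry similar
scores and neighborhood methods have signal to find, while a global column
statistic does not. The raw table mimics a FreeSurfer-derived export:
left/right paired regional features named with the eight stats keywords,
the two reference volumes (intracranial and total gray), volumes scaled by
each subject's head size, and sex / age / apoE demographics.

A separate low-rank generator (:func:`generate_low_rank`) produces the
regime that favors matrix completion, for contrast experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import DEFAULT_SCORE_SCHEMAS, FeatureMatrix, FeatureSpec, ScoreSchema
from .preprocess import DEFAULT_GRAYTOTAL_NAME, DEFAULT_ICV_NAME, preprocess_pipeline

__all__ = ["CohortSpec", "generate", "generate_normalized", "generate_low_rank",
           "DEFAULT_NOISE_SD", "DEFAULT_MISSING_FRAC"]

#: Default per-score measurement-noise standard deviations, in test points
#: (about 8% of each observed range: short-term retest variability scale).
DEFAULT_NOISE_SD: dict[str, float] = {
    "MMSE": 1.8, "GDS": 1.0, "CDR": 0.3, "NIQ": 2.3, "FAQ": 2.4,
}

#: Default fraction of each score column that is missing.
DEFAULT_MISSING_FRAC: dict[str, float] = {
    "MMSE": 0.1, "GDS": 0.1, "CDR": 0.1, "NIQ": 0.1, "FAQ": 0.1,
}

# keyword classes that come as left/right pairs vs single global features
_PAIRED_CLASSES = ("volumemm3", "area", "thickavg", "grayvol", "numvert")
_UNPAIRED_CLASSES = ("nvoxels", "nvertices", "general")


@dataclass
class CohortSpec:
    """Shape and noise levels of a synthetic cohort.

    Defaults mirror the reference cohort at one-eighth scale: 102 samples,
    74 morphometric columns, 5 latent severity groups. ``jitter_sd`` is
    the within-group morphometric scatter in latent [0, 1] units; group
    centroids are drawn uniformly on [0.2, 0.8], so neighborhoods are
    informative but groups overlap.
    """

    n_samples: int = 102
    n_morphometrics: int = 74
    n_clusters: int = 5
    score_schemas: dict[str, ScoreSchema] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_SCHEMAS)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    missing_frac: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSING_FRAC))
    jitter_sd: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_clusters > self.n_samples:
            raise ValueError("n_clusters cannot exceed n_samples")
        if self.n_morphometrics < 4:
            raise ValueError("need at least 4 morphometric features")
        for s, f in self.missing_frac.items():
            if not 0 <= f < 1:
                raise ValueError(f"missing_frac[{s}] must lie in [0, 1)")
        for s, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{s}] must be >= 0")


def _morphometric_layout(n_morphometrics: int) -> list[tuple[str, str, str]]:
    """(name, keyword_class, hemisphere) for each morphometric column.

    Region features are emitted as Left-/Right- pairs cycling through the
    paired keyword classes; leftover odd columns become unpaired global
    features. The two reference volumes are appended at the end and do not
    count toward ``n_morphometrics``.
    """
    layout: list[tuple[str, str, str]] = []
    n_pairs = n_morphometrics // 2
    n_single = n_morphometrics - 2 * n_pairs
    for i in range(n_pairs):
        kw = _PAIRED_CLASSES[i % len(_PAIRED_CLASSES)]
        base = f"Region{i:03d}_{kw}"
        layout.append((f"Left-{base}", kw, "left"))
        layout.append((f"Right-{base}", kw, "right"))
    for i in range(n_single):
        kw = _UNPAIRED_CLASSES[i % 2]  # nvoxels / nvertices
        layout.append((f"Global{i:03d}_{kw}", kw, "bilateral"))
    return layout


def _raw_scale(kw: str, latent: np.ndarray, icv: np.ndarray, tgv: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
    """Map latent [0, 1] values onto plausible raw units per keyword class."""
    if kw == "volumemm3":
        return (0.002 + 0.008 * latent) * icv
    if kw == "grayvol":
        return (0.005 + 0.02 * latent) * tgv
    if kw == "area":
        return 500.0 + 4500.0 * latent
    if kw == "thickavg":
        return 1.5 + 2.0 * latent
    # voxel / vertex counts
    return np.round(1000.0 + 19000.0 * latent)


def generate(spec: CohortSpec) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Generate a raw (un-preprocessed) cohort and its ground-truth scores.

    Returns the cohort table (scores partially masked per
    ``spec.missing_frac``) and a samples x scores DataFrame of the true
    score values in test points for **all** cells, masked ones included.
    Bit-reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n, K = spec.n_samples, spec.n_clusters
    clusters = np.resize(np.arange(K), n)
    rng.shuffle(clusters)

    layout = _morphometric_layout(spec.n_morphometrics)
    # latent centroid per (cluster, region); left/right pairs share a region
    region_keys: list[str] = []
    seen: dict[str, int] = {}
    for name, kw, hemi in layout:
        base = name.split("-", 1)[1] if hemi in ("left", "right") else name
        if base not in seen:
            seen[base] = len(seen)
        region_keys.append(base)
    n_regions = len(seen)
    centroids = rng.uniform(0.2, 0.8, size=(K, n_regions))
    latent_region = centroids[clusters] + rng.normal(0.0, spec.jitter_sd, size=(n, n_regions))
    lateral = rng.normal(0.0, 0.01, size=(n, len(layout)))  # small L/R asymmetry

    icv = rng.normal(1.5e6, 1.2e5, size=n)
    tgv = icv * 0.4 + rng.normal(0.0, 2e4, size=n)

    columns: list[np.ndarray] = []
    specs: list[FeatureSpec] = []
    for j, (name, kw, hemi) in enumerate(layout):
        latent = np.clip(latent_region[:, seen[region_keys[j]]] + lateral[:, j], 0.01, 0.99)
        columns.append(_raw_scale(kw, latent, icv, tgv, rng))
        specs.append(FeatureSpec(name, "morphometric", keyword_class=kw, hemisphere=hemi))
    columns.append(icv)
    specs.append(FeatureSpec(DEFAULT_ICV_NAME, "morphometric", keyword_class="general",
                             hemisphere="bilateral"))
    columns.append(tgv)
    specs.append(FeatureSpec(DEFAULT_GRAYTOTAL_NAME, "morphometric", keyword_class="general",
                             hemisphere="bilateral"))

    # demographics: sex (no group signal), age and apoE (weak group signal)
    sex = rng.integers(0, 2, size=n).astype(float)
    age = np.clip(70.0 + 2.2 * (clusters - (K - 1) / 2.0) + rng.normal(0, 5, size=n), 55, 90)
    p4 = 0.1 + 0.25 * clusters / max(1, K - 1)
    apoe = np.empty((n, 2))
    for a in range(2):
        pick4 = rng.random(n) < p4
        apoe[:, a] = np.where(pick4, 4.0, rng.choice([2.0, 3.0], size=n, p=[0.1, 0.9]))
    for name, col, nominal in (("sex", sex, True), ("age", age, False),
                               ("apoE_A1", apoe[:, 0], True), ("apoE_A2", apoe[:, 1], True)):
        columns.append(col)
        specs.append(FeatureSpec(name, "demographic", nominal=nominal))

    # clinical scores: evenly spaced group levels across the observed range,
    # MMSE decreasing with severity, the others increasing
    truth: dict[str, np.ndarray] = {}
    for score, schema in spec.score_schemas.items():
        lo, hi = schema.observed_range
        frac = (clusters + 0.5) / K
        if score == "MMSE":
            frac = 1.0 - frac
        level = lo + frac * (hi - lo)
        vals = level + rng.normal(0.0, spec.noise_sd.get(score, 0.0), size=n)
        vals = np.clip(vals, lo, hi)
        truth[score] = vals
        masked = rng.random(n) < spec.missing_frac.get(score, 0.0)
        col = np.where(masked, np.nan, vals)
        columns.append(col)
        specs.append(FeatureSpec(score, "clinical_score", score_schema=schema))

    values = np.column_stack(columns)
    mask = np.isfinite(values)
    sample_ids = [f"S{i:04d}" for i in range(n)]
    m = FeatureMatrix(values, mask, sample_ids, specs)
    truth_df = pd.DataFrame(truth, index=sample_ids)
    truth_df["cluster"] = clusters
    return m, truth_df


def generate_normalized(spec: CohortSpec) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Generate a cohort and run the standard preprocessing pipeline on it.

    The returned truth table is in normalized [0, 1] units (each score
    scaled on its observed range), matching the normalized cohort.
    """
    m, truth = generate(spec)
    normed = preprocess_pipeline(m)
    truth_norm = truth.copy()
    for score, schema in spec.score_schemas.items():
        lo, hi = schema.observed_range
        truth_norm[score] = (truth[score] - lo) / (hi - lo)
    truth_norm = truth_norm.loc[list(normed.sample_ids)]
    return normed, truth_norm


def generate_low_rank(
    n_samples: int = 40,
    n_features: int = 20,
    rank: int = 2,
    noise_sd: float = 0.0,
    missing_frac: float = 0.1,
    seed: int = 0,
) -> tuple[FeatureMatrix, np.ndarray]:
    """A low-rank matrix regime (favorable to matrix completion).

    Returns a FeatureMatrix of generic morphometric columns with
    ``missing_frac`` cells masked at random and the complete ground-truth
    grid.
    """
    rng = np.random.default_rng(seed)
    U = rng.normal(size=(n_samples, rank))
    V = rng.normal(size=(n_features, rank))
    full = U @ V.T + rng.normal(0.0, noise_sd, size=(n_samples, n_features))
    mask = rng.random(full.shape) >= missing_frac
    values = np.where(mask, full, np.nan)
    specs = [FeatureSpec(f"F{j:03d}_area", "morphometric", keyword_class="area",
                         hemisphere="bilateral") for j in range(n_features)]
    ids = [f"S{i:04d}" for i in range(n_samples)]
    return FeatureMatrix(values, mask, ids, specs), full
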