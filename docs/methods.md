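# Methods

## Model

The imputer treats a cohort table (samples × features) as a
recommender-system problem: patients are users, clinical tests are items,
and a missing test score is predicted from the scores of similar patients.
Two stages:

1. **Similarity.** For a target patient *x* and every other patient *y*,
   a weight w(x, y) is computed over a chosen feature-vector form —
   morphometrics only, demographics only (sex, age, apoE alleles *and* the
   other clinical scores), or their hybrid — with one of five measures:
   Pearson correlation, median-based robust correlation (Pearson with
   medians replacing means), cosine, Manhattan distance similarity
   1/Σ|xᵢ−yᵢ|, and Euclidean distance similarity 1/√Σ(xᵢ−yᵢ)². The column
   being predicted is always removed from the similarity vector, so the
   prediction never sees its own target (leave-one-out integrity).
2. **Prediction.** Candidates are the patients with the target score
   observed and a valid weight; the top BNC (best neighbor count) by
   weight — ties broken by ascending sample id for determinism — enter the
   weighted average p = Σ y_cs·w / Σ w.

Modeling assumptions: patients with similar brain morphometry have similar
clinical scores (the neighborhood premise); features are comparable after
[0, 1] normalization (so unweighted Manhattan/Euclidean distances are
meaningful); and scores missing in the table are missing at random with
respect to the similarity structure.

## Numerical and edge-case choices

* **Pairwise-complete vectors.** Missing cells are excluded per pair; a
  pair with fewer than `min_overlap` (default 2) common features, a
  zero-variance vector under a correlation measure, or a zero-norm vector
  under cosine is *invalid* and excluded from candidacy rather than given
  weight 0 — zero is a meaningful correlation, absence of evidence is not.
* **Identical vectors** under a distance measure give an infinite weight;
  the sentinel is replaced by the largest finite weight in the similarity
  matrix (per-matrix by default; a per-row variant is available since the
  convention is genuinely ambiguous).
* **Signed weights.** The weighted average uses signed weights exactly as
  written; when |Σw| < 1e−12 the prediction falls back to the unweighted
  neighbor mean and the record is flagged. An absolute-weight denominator
  is available behind a flag.
* **No chained imputation.** Values imputed in a run are never reused as
  neighbor scores in the same run, so results are independent of cell
  order.
* Per-cell impossibilities (no candidate at all) are recorded failures,
  never exceptions, so a batch run always completes.

## Preprocessing

Order: anomaly filtering → hemisphere averaging → keyword selection →
normalization. Anomaly rules (a deliberately conservative default, the
convention is not standardized): drop morphometric columns with > 20%
missing or zero variance, then rows with > 50% missing morphometrics; all
thresholds configurable. Left/right features (prefixes `Left-`/`Right-`/
`lh_`/`rh_`, case-insensitive) are averaged into bilateral features, using
the observed side when one is missing. Normalization: `volumemm3` features
are divided per sample by intracranial volume and `grayvol` features by
total gray volume before min-max scaling; everything else non-nominal is
min-max scaled over observed entries; clinical scores are scaled on their
*observed* ranges (e.g. MMSE on [8, 30]) so all five tests share one
[0, 1] scale; nominal codes (sex, apoE) are left untouched. The two
reference volumes are denominators, not predictors, and are dropped after
use (configurable). A constant column is set to 0 with a warning rather
than dropped silently.

Reporting conventions differ from the normalization convention on purpose:
the **absolute error percentage** divides by the *instrument* range
(30 for MMSE on [0, 30], 4 for CDR on [−1, 3]) and reliability thresholds
operate in raw (denormalized) test points.

## Evaluation protocol

Per trial, k originally observed cells per score (default at desk scale:
k = 25; the full-scale protocol uses 250) are emptied uniformly at random;
imputers see the masked cohort only — masked cells are hidden from
similarity vectors too. MAE, MSE, RMSE and R² compare imputed against
hidden actual values in normalized units; metrics are computed per trial
and averaged over repeats (hence `rmse = sqrt(mse)` holds per trial, not
for averaged reports). Per-repeat seeds derive as `base_seed + repeat`.
Configurations are ordered by summed per-metric ranks (MAE, RMSE
ascending; R² descending; average rank on ties; invalid metrics rank
last). MSE is computed and stored although ranking uses the three headline
metrics.

## Reliability scale

From a per-test sample of imputation errors (actual − predicted, ≥ 10
values, in points), `trusted = 2.0 × sd` and `moderate = 2.724 × sd`
(sample sd by default). Two sigma covers ≈ 95.45% of Gaussian errors —
the familiar "approximately 95% confidence" rule. The moderate multiplier
is 1.362 × the trusted one, reproducing the ratio observed across the
published per-test thresholds; the exact derivation of the published
moderate bound is not documented, so the multiplier is an explicit,
configurable modeling choice and every fitted threshold records its
provenance (n, sd, multipliers). Verdicts: d ≤ trusted → trusted;
trusted < d ≤ moderate → moderate; otherwise not trusted (repeat the
test). The shipped `REFERENCE_THRESHOLDS` are the published ADNI-1
screening values; note one row of the published worked example (MMSE 20 vs
22.555, printed "not trusted") falls *between* those bounds — it appears to
predate the two-tier scale, and the three-tier classifier here is
authoritative.

## Synthetic cohorts

The generator emulates the structure the method assumes rather than any
real cohort's marginals. Each sample belongs to one of `n_clusters` latent
severity groups (default 5). Morphometrics: per-region latent values =
group centroid (Uniform(0.2, 0.8) per region) + Gaussian jitter
(sd 0.07) + small left/right asymmetry (sd 0.01), mapped to plausible raw
units per keyword class; regional volumes scale with each subject's
intracranial volume so the reference-division step has real work to do.
Demographics: sex carries no group signal, age and apoE-4 frequency carry
weak signal. Scores: evenly spaced group levels across each instrument's
observed range (MMSE decreasing with severity, the others increasing) plus
Gaussian noise with sd ≈ 8% of the range width (MMSE 1.8, GDS 1.0, CDR
0.3, NIQ 2.3, FAQ 2.4 points — the scale of short-term retest
variability), clipped to the observed range so the declared observed range
stays truthful and normalized scores stay in [0, 1]. 10% of each score
column is masked at random. Defaults (102 samples, 74 morphometrics)
mirror the reference cohort's shape at one-eighth scale; the benchmark in
the tests uses 20 repeats with k = 25 masked cells per score and BNC 1–20.

With centroid spread ≈ 2 × jitter, groups overlap: neighborhoods are
informative but out-of-group neighbors enter the top-BNC list once BNC
approaches the per-group candidate pool (≈ (observed − k)/n_clusters ≈ 13
under the defaults). That produces the qualitative error structure the
method is known for: errors fall with BNC while neighbors stay within the
severity group, then rise as the weighted average is pulled toward other
groups' score levels — U-shaped RMSE/R² curves with the best MAE at a
"small" BNC, i.e. within one group's pool.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: integer-valued score granularity (scores here
are continuous), within-group score gradients (scores are exactly
group-determined plus noise, so the nearest neighbor is no better than any
same-group neighbor), realistic morphometric covariance and site effects,
and informative missingness. Absolute benchmark numbers on real cohorts
will differ; only the qualitative ordering claims are transportable. A
separate low-rank generator provides the complementary regime in which
matrix completion is the right model.

## Known limitations

* Distance measures treat all normalized features equally; no feature
  weighting or significance shrinkage of similarity weights.
* The imputer is cross-sectional (single visit); no longitudinal pooling.
* Regularized-EM imputation is exposed only as a plug-in slot
  (`impute_with`), not implemented.
* Low-rank completion uses a fixed rank or soft threshold; no automatic
  rank selection.
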