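"""Fit a two-sigma reliability scale and classify clinical test scores.

Imputation errors from a masking experiment (in raw test points) give a
per-test error spread; trusted = 2 x sd covers about 95% of honest
discrepancies, and moderate = 2.724 x sd marks the outer band. A clinical
score whose distance to its computer-aided prediction exceeds the moderate
bound is flagged: the test should be repeated.
"""

import numpy as np

from ducf import (
    CohortSpec,
    classify,
    fit_thresholds,
    generate_normalized,
    impute,
    make_plan,
    apply_plan,
    report,
)

spec = CohortSpec(seed=1)
m, _ = generate_normalized(spec)

# collect imputation errors over a few masking trials, in raw points
errors = {s: [] for s in spec.score_schemas}
for rep in range(5):
    plan = make_plan(m, k=25, seed=100 + rep)
    masked, actual = apply_plan(m, plan)
    result = impute(masked, measure="man", bnc=6)
    preds = {(p.target_sample, p.score_type): p.value for p in result.predictions}
    for score, ids in plan.cells.items():
        width = spec.score_schemas[score].observed_width
        for sid, a in zip(ids, actual[score]):
            if (sid, score) in preds:
                errors[score].append((a - preds[(sid, score)]) * width)

thresholds = fit_thresholds(errors)
print(f"{'score':>6} {'trusted (pts)':>14} {'moderate (pts)':>15}")
for s, th in thresholds.items():
    print(f"{s:>6} {th.trusted:>14.3f} {th.moderate:>15.3f}")

# classify a few hypothetical clinic readings against their predictions
pairs = [("MMSE", 28.0, 27.5), ("MMSE", 21.0, 26.5), ("GDS", 5.0, 1.3), ("CDR", 0.5, 0.6)]
verdicts = [classify(s, p, thresholds, t) for t, s, p in pairs]
print()
print(report(verdicts).to_string(index=False))
print()
print("'not trusted' rows flag clinical scores that disagree with the")
print("morphometrics-based prediction beyond the moderate band: repeat the test.")
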