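import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ducf import CohortSpec, FeatureMatrix, FeatureSpec, ScoreSchema, generate_normalized
from ducf.data_model import DEFAULT_SCORE_SCHEMAS

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_matrix(values, roles=None, sample_ids=None, names=None, score_names=None):
    """Build a small FeatureMatrix by hand for unit tests.

    ``roles`` is a per-column role list; score columns get the default
    schema for their name (or a generic [0, 1] schema).
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    roles = roles or ["morphometric"] * p
    names = names or [f"f{j}_area" for j in range(p)]
    specs = []
    for j, (name, role) in enumerate(zip(names, roles)):
        if role == "clinical_score":
            schema = DEFAULT_SCORE_SCHEMAS.get(name, ScoreSchema(name, (0.0, 1.0), (0.0, 1.0)))
            specs.append(FeatureSpec(name, role, score_schema=schema))
        elif role == "morphometric":
            from ducf.data_model import infer_feature_spec
            inferred = infer_feature_spec(name)
            kw = inferred.keyword_class if inferred.role == "morphometric" else "none"
            hemi = inferred.hemisphere if inferred.role == "morphometric" else "bilateral"
            specs.append(FeatureSpec(name, role, keyword_class=kw, hemisphere=hemi))
        else:
            specs.append(FeatureSpec(name, role))
    mask = np.isfinite(values)
    ids = sample_ids or [f"S{i:02d}" for i in range(n)]
    return FeatureMatrix(values, mask, ids, specs)


def random_cohort(rng, n_samples=None, n_features=None, n_scores=2, missing_frac=0.2):
    """Small random cohort with NaN-masked cells for oracle comparisons."""
    n = n_samples or int(rng.integers(5, 13))
    p = n_features or int(rng.integers(3, 7))
    values = rng.random((n, p + n_scores))
    miss = rng.random(values.shape) < missing_frac
    # keep at least 3 observed entries per column so candidates exist
    for j in range(values.shape[1]):
        if (~miss[:, j]).sum() < 3:
            miss[:3, j] = False
    values[miss] = np.nan
    names = [f"m{j}_area" for j in range(p)] + [f"score{j}" for j in range(n_scores)]
    roles = ["morphometric"] * p + ["clinical_score"] * n_scores
    return make_matrix(values, roles=roles, names=names)


@pytest.fixture(scope="session")
def default_cohort():
    """The default normalized synthetic cohort plus its ground truth."""
    return generate_normalized(CohortSpec(seed=1))
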