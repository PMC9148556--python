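import numpy as np
import pytest

from ducf import (
    average_hemispheres,
    build_normalization_plan,
    filter_anomalies,
    normalize,
    select_morphometrics,
)
from ducf.preprocess import NormalizationPlan, preprocess_pipeline

from conftest import make_matrix


def paired_matrix(values, extra=None):
    names = ["Left-Hippo_volumemm3", "Right-Hippo_volumemm3"]
    roles = ["morphometric", "morphometric"]
    if extra:
        names += extra[0]
        roles += extra[1]
    return make_matrix(values, roles=roles, names=names)


class TestHemisphereAveraging:
    def test_pair_mean(self):
        m = paired_matrix([[2.0, 4.0]])
        out = average_hemispheres(m)
        assert out.n_features == 1
        assert out.feature_specs[0].name == "Hippo_volumemm3"
        assert out.feature_specs[0].hemisphere == "bilateral"
        assert out.values[0, 0] == 3.0

    def test_one_side_missing_uses_observed_side(self):
        m = paired_matrix([[5.0, np.nan]])
        out = average_hemispheres(m)
        assert out.values[0, 0] == 5.0
        assert out.mask[0, 0]

    def test_unpaired_matrix_unchanged(self):
        m = make_matrix([[1.0, 2.0]], names=["a_area", "b_area"])
        out = average_hemispheres(m)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.feature_names == m.feature_names

    def test_halves_paired_feature_count(self):
        vals = np.arange(12.0).reshape(2, 6)
        names = ["Left-A_area", "Right-A_area", "Left-B_grayvol", "Right-B_grayvol",
                 "lh_C_thickavg", "rh_C_thickavg"]
        m = make_matrix(vals, names=names)
        out = average_hemispheres(m)
        assert out.n_features == 3

    def test_collision_with_existing_name_raises(self):
        names = ["Left-A_area", "Right-A_area", "A_area"]
        m = make_matrix([[1.0, 2.0, 3.0]], names=names)
        with pytest.raises(ValueError, match="collides"):
            average_hemispheres(m)


class TestSelectMorphometrics:
    def setup_method(self):
        vals = np.ones((2, 7))
        names = ["v1_volumemm3", "v2_volumemm3", "v3_volumemm3", "a1_area", "a2_area",
                 "age", "MMSE"]
        roles = ["morphometric"] * 5 + ["demographic", "clinical_score"]
        self.m = make_matrix(vals, roles=roles, names=names)

    def test_keyword_filter_keeps_demo_and_scores(self):
        out = select_morphometrics(self.m, {"volumemm3"})
        assert [s.name for s in out.feature_specs] == [
            "v1_volumemm3", "v2_volumemm3", "v3_volumemm3", "age", "MMSE"]

    def test_all_keywords_is_identity(self):
        from ducf import KEYWORD_CLASSES
        out = select_morphometrics(self.m, KEYWORD_CLASSES)
        assert out.feature_names == self.m.feature_names

    def test_empty_keywords_keeps_only_demographics_and_scores(self):
        out = select_morphometrics(self.m, set())
        assert [s.role for s in out.feature_specs] == ["demographic", "clinical_score"]

    def test_unknown_keyword_rejected(self):
        with pytest.raises(ValueError, match="unknown keyword"):
            select_morphometrics(self.m, {"volume"})

    def test_empty_selection_raises(self):
        m = make_matrix([[1.0]], names=["x_area"])
        with pytest.raises(ValueError, match="no features selected"):
            select_morphometrics(m, set())


class TestNormalize:
    def test_min_max_midpoint(self):
        m = make_matrix([[0.0], [5.0], [10.0]], names=["x_area"])
        out = normalize(m)
        assert out.values[1, 0] == 0.5

    def test_reference_division_then_min_max(self):
        vals = [[100.0, 1000.0], [200.0, 1000.0]]
        names = ["r_volumemm3", "EstimatedTotalIntraCranialVol"]
        m = make_matrix(vals, names=names)
        # mimic inference: volume column divided by ICV, then min-max
        from ducf.data_model import infer_feature_spec
        m.feature_specs = [infer_feature_spec(n) for n in names]
        out = normalize(m)
        np.testing.assert_allclose(out.values[:, 0], [0.0, 1.0])

    def test_clinical_score_scaled_on_observed_range(self):
        m = make_matrix([[19.0], [25.0]], roles=["clinical_score"], names=["MMSE"])
        out = normalize(m)
        assert out.values[0, 0] == pytest.approx((19 - 8) / 22)

    def test_constant_column_flagged_and_zeroed(self):
        m = make_matrix([[7.0], [7.0]], names=["x_area"])
        with pytest.warns(UserWarning, match="constant"):
            out = normalize(m)
        np.testing.assert_array_equal(out.values[:, 0], [0.0, 0.0])

    def test_nonpositive_reference_raises(self):
        names = ["r_volumemm3", "EstimatedTotalIntraCranialVol"]
        from ducf.data_model import infer_feature_spec
        m = make_matrix([[1.0, 0.0], [2.0, 5.0]], names=names)
        m.feature_specs = [infer_feature_spec(n) for n in names]
        with pytest.raises(ValueError, match="non-positive"):
            normalize(m)

    def test_nominal_untouched(self):
        m = make_matrix([[0.0], [1.0]], roles=["demographic"], names=["sex"])
        m.feature_specs = [type(m.feature_specs[0])("sex", "demographic", nominal=True)]
        out = normalize(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_observed_cells_in_unit_interval_and_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.random((8, 3)) * 50
        vals[2, 1] = np.nan
        m = make_matrix(vals)
        out = normalize(m)
        assert np.nanmin(out.values) >= 0 and np.nanmax(out.values) <= 1
        again = normalize(out)
        np.testing.assert_allclose(
            again.values[again.mask], out.values[out.mask], atol=1e-12
        )


class TestAnomalyFilter:
    def test_fully_missing_column_dropped(self):
        vals = np.ones((4, 2))
        vals[:, 1] = np.nan
        m = make_matrix(vals, names=["a_area", "b_area"])
        m.values[0, 0] = 2.0  # avoid zero variance drop of column a
        out, rep = filter_anomalies(m, col_missing_frac=0.5)
        assert rep["dropped_columns"] == ["b_area"]
        assert out.n_features == 1

    def test_permissive_thresholds_keep_everything(self):
        rng = np.random.default_rng(1)
        vals = rng.random((5, 3))
        vals[0, 0] = np.nan
        m = make_matrix(vals)
        out, rep = filter_anomalies(m, row_missing_frac=1.0, col_missing_frac=1.0,
                                    zero_variance=False)
        assert out.n_samples == 5 and out.n_features == 3
        assert not rep["dropped_columns"] and not rep["dropped_rows"]

    def test_row_above_missing_threshold_dropped(self):
        rng = np.random.default_rng(2)
        vals = rng.random((10, 5))
        vals[3, :3] = np.nan  # 60% of morphometrics missing in row 3
        m = make_matrix(vals)
        out, rep = filter_anomalies(m, row_missing_frac=0.5, col_missing_frac=1.0,
                                    zero_variance=False)
        assert out.n_samples == 9
        assert rep["dropped_rows"] == [m.sample_ids[3]]

    def test_all_rows_dropped_raises(self):
        vals = np.full((2, 2), np.nan)
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="all samples"):
            filter_anomalies(m, row_missing_frac=0.1, col_missing_frac=1.0,
                             zero_variance=False)


def test_pipeline_drops_reference_columns(default_cohort):
    m, _ = default_cohort
    names = set(m.feature_names)
    assert "EstimatedTotalIntraCranialVol" not in names
    assert "TotalGrayVol" not in names


def test_plan_maps_keywords_to_references():
    names = ["x_volumemm3", "y_grayvol", "z_area",
             "EstimatedTotalIntraCranialVol", "TotalGrayVol", "sex"]
    roles = ["morphometric"] * 5 + ["demographic"]
    m = make_matrix(np.ones((2, 6)), roles=roles, names=names)
    from ducf.data_model import infer_feature_spec
    m.feature_specs = [infer_feature_spec(n) for n in names]
    plan = build_normalization_plan(m)
    assert plan.rules["x_volumemm3"] == ("divide_by_reference", "EstimatedTotalIntraCranialVol")
    assert plan.rules["y_grayvol"] == ("divide_by_reference", "TotalGrayVol")
    assert plan.rules["z_area"] == ("min_max", None)
    assert plan.rules["sex"] == ("none", None)
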