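import numpy as np
import pytest

from ducf import impute, predict, select_neighbors
from ducf.imputer import FEATURE_FORMS, Neighbor, NeighborSet, feature_form_columns
from ducf.similarity import MEASURES

from conftest import make_matrix, random_cohort
from oracles import bruteforce_impute


def neighbor_set(pairs):
    nbs = [Neighbor(f"S{i}", w, s) for i, (w, s) in enumerate(pairs)]
    return NeighborSet("T", "MMSE", nbs, len(nbs))


class TestPredict:
    def test_weighted_average(self):
        ns = neighbor_set([(3.0, 1.0), (1.0, 0.0)])
        assert predict(ns).value == pytest.approx(0.75)

    def test_single_neighbor_returns_its_score(self):
        ns = neighbor_set([(42.0, 0.37)])
        assert predict(ns).value == pytest.approx(0.37)

    def test_equal_weights_reduce_to_mean(self):
        ns = neighbor_set([(2.0, 0.2), (2.0, 0.4), (2.0, 0.6)])
        assert predict(ns).value == pytest.approx(0.4)

    def test_zero_weight_sum_falls_back_to_mean(self):
        ns = neighbor_set([(1.0, 0.0), (-1.0, 1.0)])
        p = predict(ns)
        assert p.fallback_mean and p.value == pytest.approx(0.5)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            predict(NeighborSet("T", "MMSE", [], 3))


class TestSelectNeighbors:
    def _matrix(self):
        # col 0: morphometric; col 1: score observed for all but the target
        vals = np.array([[0.0, np.nan], [0.1, 0.2], [0.5, 0.4], [0.9, 0.6]])
        return make_matrix(vals, roles=["morphometric", "clinical_score"],
                           names=["m_area", "score0"])

    def test_top_k_by_weight(self):
        m = self._matrix()
        weights = np.array([np.nan, 0.9, 0.5, 0.1])
        ns = select_neighbors(m, m.sample_ids[0], "score0", weights, bnc=2)
        assert [nb.sample_id for nb in ns.neighbors] == [m.sample_ids[1], m.sample_ids[2]]
        assert [nb.score for nb in ns.neighbors] == [0.2, 0.4]

    def test_bnc_larger_than_pool_returns_all(self):
        m = self._matrix()
        ns = select_neighbors(m, m.sample_ids[0], "score0",
                              np.array([np.nan, 0.9, 0.5, 0.1]), bnc=100)
        assert len(ns.neighbors) == 3

    def test_tie_broken_by_ascending_sample_id(self):
        m = self._matrix()
        ns = select_neighbors(m, m.sample_ids[0], "score0",
                              np.array([np.nan, 0.5, 0.5, 0.1]), bnc=1)
        assert ns.neighbors[0].sample_id == m.sample_ids[1]

    def test_no_candidates_raises(self):
        vals = np.array([[0.0, np.nan], [0.1, np.nan]])
        m = make_matrix(vals, roles=["morphometric", "clinical_score"],
                        names=["m_area", "score0"])
        with pytest.raises(ValueError, match="no neighbor"):
            select_neighbors(m, m.sample_ids[0], "score0", np.array([np.nan, 1.0]), bnc=1)


class TestImpute:
    def test_no_missing_scores_is_identity(self):
        m = make_matrix(np.array([[0.1, 0.2], [0.3, 0.4]]),
                        roles=["morphometric", "clinical_score"], names=["m_area", "score0"])
        res = impute(m, "man", bnc=1)
        assert res.predictions == []
        np.testing.assert_array_equal(res.matrix.values, m.values)

    def test_two_nearest_weighted_mean(self):
        # 5 samples, 2 morphometrics, 1 missing score; MAN, bnc=2
        vals = np.array([
            [0.10, 0.20, np.nan],
            [0.12, 0.22, 0.30],
            [0.15, 0.24, 0.50],
            [0.80, 0.90, 0.90],
            [0.70, 0.85, 0.80],
        ])
        m = make_matrix(vals, roles=["morphometric", "morphometric", "clinical_score"],
                        names=["a_area", "b_area", "MMSE"])
        res = impute(m, "man", bnc=2)
        w1 = 1.0 / (0.02 + 0.02)   # sample 1
        w2 = 1.0 / (0.05 + 0.04)   # sample 2
        expected = (w1 * 0.30 + w2 * 0.50) / (w1 + w2)
        assert res.predictions[0].value == pytest.approx(expected, abs=1e-12)
        assert res.matrix.mask[0, 2]
        assert res.matrix.imputed[0, 2]

    def test_all_candidates_missing_is_recorded_failure(self):
        vals = np.array([[0.1, np.nan], [0.2, np.nan], [0.3, np.nan]])
        m = make_matrix(vals, roles=["morphometric", "clinical_score"],
                        names=["m_area", "score0"])
        res = impute(m, "man", bnc=2)
        assert res.predictions == []
        assert len(res.failures) == 3
        assert "no valid neighbor" in res.failures[0].reason

    def test_non_score_missing_cells_untouched(self):
        vals = np.array([[np.nan, 0.2, 0.5], [0.4, 0.1, 0.6], [0.5, 0.2, np.nan]])
        m = make_matrix(vals, roles=["morphometric", "morphometric", "clinical_score"],
                        names=["a_area", "b_area", "score0"])
        res = impute(m, "euc", bnc=1)
        assert not res.matrix.mask[0, 0]
        assert res.matrix.mask[2, 2]

    def test_convexity_with_positive_weights(self):
        rng = np.random.default_rng(11)
        m = random_cohort(rng, n_samples=10)
        res = impute(m, "man", bnc=4)
        for p in res.predictions:
            cs = m.score_columns()[p.score_type]
            obs = m.values[m.mask[:, cs], cs]
            assert obs.min() - 1e-12 <= p.value <= obs.max() + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        m = random_cohort(rng, n_samples=9)
        res = impute(m, "euc", bnc=3)
        perm = rng.permutation(m.n_samples)
        m2 = make_matrix(m.values[perm], roles=[s.role for s in m.feature_specs],
                         names=m.feature_names,
                         sample_ids=[m.sample_ids[i] for i in perm])
        res2 = impute(m2, "euc", bnc=3)
        a = {(p.target_sample, p.score_type): p.value for p in res.predictions}
        b = {(p.target_sample, p.score_type): p.value for p in res2.predictions}
        assert a.keys() == b.keys()
        for key in a:
            assert b[key] == pytest.approx(a[key], abs=1e-12)

    def test_constant_weights_equal_attribute_mean(self):
        # cosine similarity of identical morphometric vectors: every weight 1
        vals = np.array([
            [0.5, 0.5, np.nan],
            [0.5, 0.5, 0.2],
            [0.5, 0.5, 0.4],
            [0.5, 0.5, 0.9],
        ])
        m = make_matrix(vals, roles=["morphometric", "morphometric", "clinical_score"],
                        names=["a_area", "b_area", "score0"])
        res = impute(m, "cos", bnc=3, feature_form="morphometrics")
        assert res.predictions[0].value == pytest.approx(np.mean([0.2, 0.4, 0.9]))

    def test_imputed_values_not_reused_within_run(self):
        # two adjacent targets share the same score column: each prediction
        # must be formed from the originally observed neighbors only — had
        # sample 0's fresh imputation entered sample 1's neighborhood (at
        # Manhattan weight 1/0.01) the second prediction would shift
        vals = np.array([
            [0.70, 0.5, np.nan],
            [0.71, 0.5, np.nan],
            [0.50, 0.5, 0.4],
            [0.90, 0.5, 0.8],
        ])
        m = make_matrix(vals, roles=["morphometric", "morphometric", "clinical_score"],
                        names=["a_area", "b_area", "score0"])
        res = impute(m, "man", bnc=2)
        by_id = {p.target_sample: p.value for p in res.predictions}
        w2, w3 = 1 / 0.20, 1 / 0.20
        assert by_id[m.sample_ids[0]] == pytest.approx(
            (w2 * 0.4 + w3 * 0.8) / (w2 + w3), abs=1e-12)
        w2, w3 = 1 / 0.21, 1 / 0.19
        assert by_id[m.sample_ids[1]] == pytest.approx(
            (w2 * 0.4 + w3 * 0.8) / (w2 + w3), abs=1e-12)

    def test_unknown_feature_form_rejected(self):
        m = random_cohort(np.random.default_rng(1))
        with pytest.raises(ValueError, match="feature form"):
            impute(m, "man", bnc=1, feature_form="everything")


class TestOracleEquivalence:
    @pytest.mark.parametrize("measure", MEASURES)
    def test_matches_bruteforce_enumerate_sort_average(self, measure):
        rng = np.random.default_rng(77)
        for _ in range(20):
            m = random_cohort(rng)
            for bnc in (1, 3, 8):
                res = impute(m, measure, bnc=bnc)
                expected = bruteforce_impute(
                    m.values, m.mask, m.score_columns(),
                    feature_form_columns(m, "hybrid"), measure, bnc, m.sample_ids)
                got = {(p.target_sample, p.score_type): p.value for p in res.predictions}
                for key, val in expected.items():
                    if np.isnan(val):
                        assert key not in got
                    else:
                        assert got[key] == pytest.approx(val, abs=1e-10)


def test_feature_form_columns_roles(default_cohort):
    m, _ = default_cohort
    morph = feature_form_columns(m, "morphometrics")
    demo = feature_form_columns(m, "demographics")
    hybrid = feature_form_columns(m, "hybrid")
    assert set(hybrid) == set(morph) | set(demo)
    assert all(m.feature_specs[j].role == "morphometric" for j in morph)
    # demographics deliberately include the clinical scores
    assert any(m.feature_specs[j].role == "clinical_score" for j in demo)
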