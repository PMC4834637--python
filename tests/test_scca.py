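"""Tests for the sparse CCA feature-selection machinery."""

import numpy as np
import pytest

from fcbiomarker import scca
from tests.conftest import attribute_matrix


def grid_search_projection(a, c, step=1e-6):
    """Dense grid over the soft threshold: the independent oracle.

    Scans deltas from 0 upward (step relative to max|a|) and returns the
    normalized soft-thresholded vector at the first grid point satisfying
    the L1 bound.
    """
    amax = np.abs(a).max()
    deltas = np.arange(0.0, amax, step * amax)
    for chunk in np.array_split(deltas, max(1, len(deltas) // 50_000)):
        v = np.sign(a) * np.maximum(np.abs(a)[None, :] - chunk[:, None], 0)
        nrm = np.linalg.norm(v, axis=1)
        ok = nrm > 0
        v[ok] /= nrm[ok, None]
        feasible = ok & (np.abs(v).sum(axis=1) <= c)
        if feasible.any():
            i = int(np.argmax(feasible))
            return chunk[i], v[i]
    return None


class TestL1L2Project:
    def test_inactive_constraint_returns_normalized_input(self, rng):
        a = rng.standard_normal(10)
        c = np.abs(a).sum() / np.linalg.norm(a) + 0.1
        v = scca.l1_l2_project(a, c)
        np.testing.assert_allclose(v, a / np.linalg.norm(a), atol=1e-9)

    def test_c_equal_one_gives_single_spike(self, rng):
        a = rng.standard_normal(20)
        v = scca.l1_l2_project(a, 1.0)
        i = np.argmax(np.abs(a))
        assert np.count_nonzero(v) == 1
        assert v[i] == pytest.approx(np.sign(a[i]), abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            a = rng.standard_normal(12)
            v = scca.l1_l2_project(a, 2.0)
            delta, v_oracle = grid_search_projection(a, 2.0)
            assert np.abs(v).sum() == pytest.approx(np.abs(v_oracle).sum(), abs=1e-4)
            assert a @ v == pytest.approx(a @ v_oracle, abs=1e-4)

    def test_signs_follow_input(self, rng):
        a = rng.standard_normal(15)
        v = scca.l1_l2_project(a, 1.5)
        nz = v != 0
        assert np.all(np.sign(v[nz]) == np.sign(a[nz]))

    def test_constraints_satisfied(self, rng):
        for c in (1.0, 1.5, 2.5, 4.0):
            a = rng.standard_normal(30)
            v = scca.l1_l2_project(a, c)
            assert np.linalg.norm(v) <= 1 + 1e-9
            assert np.abs(v).sum() <= c + 1e-6

    def test_all_zero_input_returns_zero(self):
        assert np.all(scca.l1_l2_project(np.zeros(5), 2.0) == 0)

    def test_infeasible_bound_rejected(self):
        with pytest.raises(ValueError):
            scca.l1_l2_project(np.ones(3), 0.5)


class TestStandardize:
    def test_training_columns_centred_and_scaled(self, rng):
        x1 = rng.standard_normal((40, 10))
        x2 = rng.standard_normal((40, 25))
        cohort = scca.standardize(x1, x2)
        assert np.abs(cohort.x1.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(cohort.x1.std(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(cohort.x2.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_inert_and_flagged(self, rng):
        x1 = rng.standard_normal((30, 10))
        x1[:, 3] = 2.0  # single-site style constant flag
        cohort = scca.standardize(x1, rng.standard_normal((30, 5)))
        assert 3 in cohort.constant_columns["x1"]
        assert np.all(cohort.x1[:, 3] == 0)


class TestSccaFit:
    def test_q_components_for_ten_attributes(self, small_planted_cohort):
        attrs, fc, _ = small_planted_cohort
        cohort = scca.standardize(attribute_matrix(attrs), fc)
        res = scca.scca_fit(cohort, 0.3, 0.3)
        assert res.v1.shape == (10, 10)
        assert res.v2.shape == (fc.shape[1], 10)

    def test_constraint_satisfaction_each_component(self, small_planted_cohort):
        attrs, fc, _ = small_planted_cohort
        cohort = scca.standardize(attribute_matrix(attrs), fc)
        for lam1, lam2 in [(0.1, 0.1), (0.3, 0.7), (0.9, 0.9)]:
            res = scca.scca_fit(cohort, lam1, lam2)
            c1 = max(1.0, lam1 * np.sqrt(10))
            c2 = max(1.0, lam2 * np.sqrt(fc.shape[1]))
            for k in range(10):
                for v, c in ((res.v1[:, k], c1), (res.v2[:, k], c2)):
                    if np.any(v):
                        assert np.linalg.norm(v) <= 1 + 1e-9
                        assert np.abs(v).sum() <= c + 1e-6

    def test_rank_one_planted_recovery(self, rng):
        n = 300
        x1 = rng.standard_normal((n, 4))
        x1[:, 0] = rng.integers(0, 2, n)  # diagnosis
        x2 = rng.standard_normal((n, 12)) * 0.5
        x2[:, 5] += 2.0 * x1[:, 0]
        cohort = scca.standardize(x1, x2)
        res = scca.scca_fit(cohort, 0.25, 0.25)
        assert np.flatnonzero(res.v1[:, 0]).tolist() == [0]
        assert 5 in np.flatnonzero(res.v2[:, 0])

    def test_unconstrained_fit_matches_svd_oracle(self, rng):
        x1 = rng.standard_normal((50, 3))
        x2 = rng.standard_normal((50, 4))
        cohort = scca.standardize(x1, x2)
        res = scca.scca_fit(cohort, 1.0, 1.0)
        u, s, vt = np.linalg.svd(cohort.x1.T @ cohort.x2)
        cos1 = abs(res.v1[:, 0] @ u[:, 0])
        cos2 = abs(res.v2[:, 0] @ vt[0])
        assert cos1 >= 0.999 and cos2 >= 0.999
        assert res.canonical_values[0] == pytest.approx(s[0], rel=1e-3)

    def test_full_deflation_exhausts_cross_product(self, rng):
        x1 = rng.standard_normal((40, 3))
        x2 = rng.standard_normal((40, 4))
        cohort = scca.standardize(x1, x2)
        res = scca.scca_fit(cohort, 1.0, 1.0)
        s = cohort.x1.T @ cohort.x2
        for k in range(3):
            s = s - res.canonical_values[k] * np.outer(res.v1[:, k], res.v2[:, k])
        assert np.linalg.norm(s) < 1e-6

    def test_monotone_sparsity_in_lambda2(self, small_planted_cohort):
        attrs, fc, _ = small_planted_cohort
        cohort = scca.standardize(attribute_matrix(attrs), fc)
        supports = []
        for lam2 in (0.1, 0.3, 0.5, 0.7, 0.9):
            res = scca.scca_fit(cohort, 0.1, lam2)
            supports.append(np.count_nonzero(res.v2[:, 0]))
        assert all(a <= b for a, b in zip(supports, supports[1:]))

    def test_bad_lambda_rejected(self, rng):
        cohort = scca.standardize(rng.standard_normal((20, 3)), rng.standard_normal((20, 4)))
        with pytest.raises(ValueError):
            scca.scca_fit(cohort, 0.0, 0.5)


class TestDiagnosticFeatureUnion:
    def _result(self, v1, v2):
        q = v1.shape[1]
        return scca.SccaResult(
            v1=v1, v2=v2, canonical_values=np.ones(q), lambda1=0.5, lambda2=0.5
        )

    def test_mixed_loading_column_is_not_diagnostic(self):
        v1 = np.zeros((4, 2))
        v1[0, 0] = 0.7
        v1[1, 0] = 0.7  # loads on site too -> not diagnostic
        v1[0, 1] = 1.0  # diagnosis only -> diagnostic
        v2 = np.zeros((6, 2))
        v2[2, 0] = 1.0
        v2[4, 1] = 0.5
        sel = scca.diagnostic_feature_union(self._result(v1, v2))
        assert sel.selected_indices.tolist() == [4]

    def test_no_diagnostic_column_gives_empty_selection(self):
        v1 = np.zeros((3, 1))
        v1[1, 0] = 1.0
        v2 = np.ones((5, 1))
        sel = scca.diagnostic_feature_union(self._result(v1, v2))
        assert sel.m == 0
        assert sel.selected_indices.size == 0

    def test_union_sums_xi_across_results(self):
        def res(support, weights):
            v1 = np.zeros((3, 1))
            v1[0, 0] = 1.0
            v2 = np.zeros((6, 1))
            v2[support, 0] = weights
            return self._result(v1, v2)

        sel = scca.diagnostic_feature_union(
            [res([1, 3], [0.5, 0.2]), res([3, 5], [0.3, 0.4])]
        )
        assert sel.selected_indices.tolist() == [1, 3, 5]
        assert sel.xi[3] == pytest.approx(0.5)

    def test_nv_exclusion_at_sparse_grid_cell(self):
        """Site-linked FCs are not preferentially selected by the diagnostic union.

        On a cohort with planted diagnosis FCs and independent site-effect
        FCs, the sparsest grid cell recovers >= 80% of planted FCs while
        selecting site-only FCs at no more than the generic-noise rate and
        below 5% overall.
        """
        from fcbiomarker import synthetic

        attrs, fc, truth = synthetic.planted_cohort(
            n_subjects=400, n_fc=2000, seed=2024, medication_rates=(0, 0)
        )
        cohort = scca.standardize(attribute_matrix(attrs), fc)
        res = scca.scca_fit(cohort, 0.1, 0.1)
        sel = set(scca.diagnostic_feature_union(res).selected_indices.tolist())
        planted = set(truth.diagnosis_fc_indices.tolist())
        site = set(truth.nuisance_map["site_b"][0].tolist())
        noise = set(range(2000)) - planted - site
        assert len(sel & planted) >= 0.8 * len(planted)
        site_rate = len(sel & site) / len(site)
        noise_rate = len(sel & noise) / len(noise)
        assert site_rate <= 0.05
        assert site_rate <= noise_rate + 0.05


class TestProject:
    def test_identity_selection(self, rng):
        x = rng.standard_normal(8)
        sel = scca.FeatureSelection(xi=np.ones(8), selected_indices=np.arange(8))
        np.testing.assert_array_equal(scca.project(x, sel), x)

    def test_empty_selection(self, rng):
        sel = scca.FeatureSelection(xi=np.zeros(8), selected_indices=np.array([], dtype=int))
        assert scca.project(rng.standard_normal(8), sel).shape == (0,)

    def test_specific_indices(self):
        x = np.arange(10.0)
        sel = scca.FeatureSelection(
            xi=np.zeros(10), selected_indices=np.array([2, 7])
        )
        np.testing.assert_array_equal(scca.project(x, sel), [2.0, 7.0])

    def test_out_of_range_rejected(self):
        sel = scca.FeatureSelection(xi=np.zeros(3), selected_indices=np.array([9]))
        with pytest.raises(IndexError):
            scca.project(np.zeros(5), sel)
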