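"""Single-subject ΔPCC perturbation networks and their MC significance."""

import numpy as np
import pytest

from petnets import (
    DeltaPCCConfig,
    DeltaPCCMatrix,
    RegionSUVTable,
    ThresholdCurve,
    average_network,
    calibrate_threshold,
    delta_network,
    deltapcc_pipeline,
    pairwise_matrix,
    pearson,
    perturbation_network,
    reference_network,
)


def _table(values, regions, groups=None, ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return RegionSUVTable(
        subject_ids=ids or [f"s{i}" for i in range(n)],
        group_labels=groups or ["control"] * n,
        region_labels=regions,
        values=values,
    )


class TestReferenceAndPerturbation:
    def test_identical_region_columns_correlate_fully(self):
        col = np.array([1.0, 2.0, 4.0])
        t = _table(np.column_stack([col, col, 2 * col]), list("abc"))
        ref = reference_network(t)
        assert ref.pair("a", "b")[0] == pytest.approx(1.0)

    def test_negated_deviations_give_minus_one(self):
        col = np.array([1.0, 2.0, 4.0])
        t = _table(np.column_stack([col, 2 * col.mean() - col, col]), list("abc"))
        assert reference_network(t).pair("a", "b")[0] == pytest.approx(-1.0)

    def test_matches_brute_force_pairwise_pearson(self, rng):
        vals = rng.uniform(0.5, 5.0, size=(3, 3))
        t = _table(vals, list("abc"))
        ref = reference_network(t)
        for i, a in enumerate("abc"):
            for j, b in enumerate("abc"):
                if i != j:
                    assert ref.r_matrix[i, j] == pytest.approx(
                        pearson(vals[:, i], vals[:, j]), abs=1e-12)

    def test_mixed_group_table_rejected(self):
        t = _table(np.ones((4, 3)) + np.eye(4, 3), list("abc"),
                   groups=["control"] * 3 + ["rifampicin"])
        with pytest.raises(ValueError, match="mixes groups"):
            reference_network(t)

    def test_perturbation_equals_recomputation_on_concatenated_table(self, rng):
        ref_vals = rng.uniform(0.5, 5.0, size=(5, 4))
        row = rng.uniform(0.5, 5.0, size=4)
        t = _table(ref_vals, list("abcd"))
        pert = perturbation_network(t, "new", row)
        direct = pairwise_matrix(np.vstack([ref_vals, row]).T, list("abcd"))
        np.testing.assert_allclose(pert.r_matrix, direct.r_matrix, atol=1e-12)

    def test_three_point_correlation_closed_form(self):
        # n=2 reference + 1 added: r of ((0,0),(1,2),(2,1)) = 0.5
        t = _table([[0.0, 0.0], [1.0, 2.0]], ["x", "y"])
        pert = perturbation_network(t, "p", [2.0, 1.0])
        assert pert.pair("x", "y")[0] == pytest.approx(0.5)

    def test_duplicate_subject_id_rejected(self):
        t = _table(np.random.default_rng(1).random((3, 3)) + 0.1, list("abc"))
        with pytest.raises(ValueError, match="already among"):
            perturbation_network(t, "s0", [1.0, 2.0, 3.0])


class TestDeltaNetwork:
    def _corr(self, rng, n=3):
        return pairwise_matrix(rng.uniform(0, 1, size=(n, 6)), tuple("abc"[:n]))

    def test_self_difference_is_zero(self, rng):
        a = self._corr(rng)
        d = delta_network(a, a)
        np.testing.assert_allclose(d.delta, 0.0)

    def test_antisymmetry(self, rng):
        a, b = self._corr(rng), self._corr(rng)
        np.testing.assert_allclose(
            delta_network(a, b).delta, -delta_network(b, a).delta, atol=1e-15)

    def test_elementwise_difference(self, rng):
        a, b = self._corr(rng), self._corr(rng)
        d = delta_network(a, b)
        np.testing.assert_allclose(d.delta, b.r_matrix - a.r_matrix, atol=1e-15)

    def test_region_mismatch_rejected(self, rng):
        a = self._corr(rng, 3)
        b = pairwise_matrix(rng.uniform(0, 1, size=(3, 6)), tuple("xyz"))
        with pytest.raises(ValueError, match="region sets"):
            delta_network(a, b)


class TestCalibration:
    def test_reproducible_under_seed(self):
        a = calibrate_threshold(13, 0.0, n_replicates=10_000, seed=7)
        b = calibrate_threshold(13, 0.0, n_replicates=10_000, seed=7)
        assert a == b

    def test_perfect_reference_correlation_limit(self):
        # adding one point to a near-perfectly correlated sample barely moves r
        crit = calibrate_threshold(13, 0.999, n_replicates=20_000, seed=0)
        assert crit < 0.02

    def test_large_n_shrinks_threshold(self):
        crit = calibrate_threshold(1000, 0.0, n_replicates=20_000, seed=0)
        assert crit < 0.02

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(2, 0.0)
        with pytest.raises(ValueError):
            calibrate_threshold(13, 1.0)
        with pytest.raises(ValueError):
            calibrate_threshold(13, 0.0, alpha=0.0)
        with pytest.raises(ValueError):
            calibrate_threshold(13, 0.0, n_replicates=100)

    def test_curve_interpolates_its_own_grid(self):
        curve = ThresholdCurve.calibrate(13, rho_grid=np.array([0.0, 0.5, 0.9]),
                                         n_replicates=20_000, seed=1)
        np.testing.assert_allclose(curve.critical(curve.rho_grid),
                                   curve.critical_values)
        # sign of rho is irrelevant under the bivariate-normal null
        assert curve.critical(-0.5) == curve.critical(0.5)

    def test_pvalue_consistent_with_critical_value(self):
        curve = ThresholdCurve.calibrate(13, alpha=0.05,
                                         rho_grid=np.array([0.0, 0.9]),
                                         n_replicates=50_000, seed=2)
        crit = curve.critical_values[0]
        assert curve.p_value(crit * 1.05, 0.0) < 0.05
        assert curve.p_value(crit * 0.9, 0.0) > 0.05


class TestAveraging:
    def _delta(self, mat, thr, sid="r1"):
        return DeltaPCCMatrix(tuple("abc"), np.asarray(mat, float), sid, 13, thr)

    def test_all_subthreshold_gives_zero_matrix(self):
        m = [[0, 0.1, -0.1], [0.1, 0, 0.05], [-0.1, 0.05, 0]]
        avg = average_network([self._delta(m, 0.2)])
        np.testing.assert_allclose(avg, 0.0)

    def test_single_supra_threshold_matrix_returned_as_is(self):
        m = np.array([[0, 0.5, -0.6], [0.5, 0, 0.7], [-0.6, 0.7, 0]])
        avg = average_network([self._delta(m, 0.2)])
        np.testing.assert_allclose(avg, m)

    def test_zeroed_subjects_attenuate_the_mean(self):
        hot = np.array([[0, 0.6, 0.0], [0.6, 0, 0.0], [0.0, 0.0, 0]])
        cold = np.zeros((3, 3))
        avg = average_network([self._delta(hot, 0.2, "r1"),
                               self._delta(cold, 0.2, "r2")])
        np.testing.assert_allclose(avg, hot / 2)

    def test_region_mismatch_rejected(self):
        a = self._delta(np.zeros((3, 3)), 0.2)
        b = DeltaPCCMatrix(tuple("xyz"), np.zeros((3, 3)), "r2", 13, 0.2)
        with pytest.raises(ValueError, match="region sets"):
            average_network([a, b])


class TestPipeline:
    CFG = DeltaPCCConfig(n_replicates=20_000, seed=0)

    def test_single_perturbation_subject_average_is_its_matrix(self, rng):
        vals = rng.uniform(1.0, 3.0, size=(6, 4))
        t = _table(vals, list("abcd"), groups=["control"] * 5 + ["rifampicin"])
        res = deltapcc_pipeline(t, self.CFG)
        assert len(res.per_subject) == 1
        np.testing.assert_allclose(res.averaged, res.per_subject[0].thresholded())

    def test_order_of_perturbation_subjects_irrelevant(self, rng):
        vals = rng.uniform(1.0, 3.0, size=(8, 4))
        groups = ["control"] * 5 + ["rifampicin"] * 3
        t = _table(vals, list("abcd"), groups=groups)
        res1 = deltapcc_pipeline(t, self.CFG)
        order = [0, 1, 2, 3, 4, 7, 5, 6]  # shuffle perturbation rows only
        t2 = _table(vals[order], list("abcd"), groups=[groups[i] for i in order],
                    ids=[f"s{i}" for i in order])
        res2 = deltapcc_pipeline(t2, self.CFG)
        np.testing.assert_allclose(res1.averaged, res2.averaged, atol=1e-12)

    def test_missing_perturbation_group_rejected(self, rng):
        t = _table(rng.uniform(1, 2, size=(5, 4)), list("abcd"))
        with pytest.raises(ValueError, match="perturbation"):
            deltapcc_pipeline(t, self.CFG)

    def test_null_cohort_pooled_deltas_centre_at_zero(self):
        from petnets import generate_cohort, make_fixture

        cohort = generate_cohort(make_fixture("null", seed=5))
        res = deltapcc_pipeline(cohort.suv_table, self.CFG)
        assert abs(np.median(res.pooled_deltas)) < 0.05
        # and nearly everything is below threshold
        assert np.mean(np.abs(res.averaged) > res.threshold) < 0.1

    def test_liver_effect_detected_in_average(self, default_cohort):
        res = deltapcc_pipeline(default_cohort.suv_table, self.CFG)
        labels = list(res.region_labels)
        liv = labels.index("liver")
        sig = res.significant_average()
        assert sig[liv].any()

    def test_fixed_threshold_mode(self, default_cohort):
        cfg = DeltaPCCConfig(threshold_mode="fixed", fixed_threshold=0.18)
        res = deltapcc_pipeline(default_cohort.suv_table, cfg)
        off_diag = ~np.eye(len(res.region_labels), dtype=bool)
        assert np.all(res.threshold[off_diag] == 0.18)

    def test_fdr_mode_is_more_conservative_under_null(self):
        from petnets import generate_cohort, make_fixture

        cohort = generate_cohort(make_fixture("null", seed=3))
        plain = deltapcc_pipeline(cohort.suv_table, self.CFG)
        fdr = deltapcc_pipeline(
            cohort.suv_table,
            DeltaPCCConfig(n_replicates=20_000, seed=0, fdr=True),
        )
        n_plain = sum(np.count_nonzero(d.thresholded()) for d in plain.per_subject)
        n_fdr = sum(np.count_nonzero(d.thresholded()) for d in fdr.per_subject)
        assert n_fdr <= n_plain
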