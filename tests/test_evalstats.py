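import numpy as np
import pytest

import petcorr as pc
from petcorr import evalstats as ev
from petcorr.phantom import Lesion
from petcorr.volume import ImageVolume, VolumeError


def _vol(arr, role="activity_bqml"):
    return ImageVolume(np.asarray(arr, dtype=float), role=role)


def _metrics_oracle(re_values):
    """Naive per-voxel loop implementation of the error summaries."""
    n = len(re_values)
    mu = sum(re_values) / n
    var = sum((v - mu) ** 2 for v in re_values) / n
    mape = 100.0 * sum(abs(v) for v in re_values) / n
    rmspe = 100.0 * (mu * mu + var) ** 0.5
    return mape, rmspe


class TestRelativeErrorImage:
    def test_identical_images_zero(self):
        img = _vol(np.full((3, 3, 1), 1000.0))
        re, mask = ev.relative_error_image(img, img, np.ones((3, 3, 1), bool))
        assert (re.data == 0).all() and mask.all()

    def test_substitution(self):
        re, _ = ev.relative_error_image(_vol([[[1200.0]]]), _vol([[[1000.0]]]),
                                        np.ones((1, 1, 1), bool))
        assert re.data[0, 0, 0] == pytest.approx(0.2)

    def test_floor_excludes_voxels(self):
        gs = _vol([[[200.0, 1000.0]]])
        x = _vol([[[400.0, 1100.0]]])
        re, mask = ev.relative_error_image(x, gs, np.ones((1, 1, 2), bool),
                                           act_floor_bqml=300.0)
        assert not mask[0, 0, 0] and mask[0, 0, 1]

    def test_empty_evaluable_set_raises(self):
        gs = _vol(np.full((2, 2, 1), 10.0))
        with pytest.raises(VolumeError):
            ev.relative_error_image(gs, gs, np.ones((2, 2, 1), bool),
                                    act_floor_bqml=300.0)


class TestComputeMetrics:
    @pytest.mark.parametrize("re_vals,exp_mape,exp_rmspe", [
        ([0.1, 0.1, 0.1], 10.0, 10.0),
        ([0.1, -0.1], 10.0, 10.0),
        ([0.3, 0.1], 20.0, 100 * np.sqrt(0.2 ** 2 + 0.1 ** 2)),
    ])
    def test_hand_computed_cases(self, re_vals, exp_mape, exp_rmspe):
        re = _vol(np.asarray(re_vals).reshape(-1, 1, 1), role="dimensionless")
        m = ev.compute_metrics(re, np.ones(re.shape, bool))
        assert m.mape == pytest.approx(exp_mape)
        assert m.rmspe == pytest.approx(exp_rmspe)
        assert m.rmspe >= m.mape

    def test_matches_loop_oracle_on_random_fields(self, rng):
        for _ in range(20):
            vals = rng.normal(0, 0.2, size=1000)
            re = _vol(vals.reshape(10, 10, 10), role="dimensionless")
            m = ev.compute_metrics(re, np.ones((10, 10, 10), bool))
            mape, rmspe = _metrics_oracle(list(vals))
            assert m.mape == pytest.approx(mape, rel=1e-10)
            assert m.rmspe == pytest.approx(rmspe, rel=1e-10)

    def test_rmspe_equals_rms_identity(self, rng):
        vals = rng.normal(0, 0.3, size=500)
        re = _vol(vals.reshape(5, 10, 10), role="dimensionless")
        m = ev.compute_metrics(re, np.ones((5, 10, 10), bool))
        assert m.rmspe == pytest.approx(100 * np.sqrt(np.mean(vals ** 2)),
                                        rel=1e-12)

    def test_scale_invariance(self, rng):
        a = rng.uniform(500, 2000, (6, 6, 2))
        b = rng.uniform(500, 2000, (6, 6, 2))
        mask = np.ones((6, 6, 2), bool)
        m1 = ev.evaluate_pair(_vol(a), _vol(b), mask)
        m2 = ev.evaluate_pair(_vol(3.7 * a), _vol(3.7 * b), mask,
                              act_floor_bqml=3.7 * 300.0)
        assert m1.mape == pytest.approx(m2.mape, rel=1e-12)
        assert m1.rmspe == pytest.approx(m2.rmspe, rel=1e-12)


class TestLesionMetrics:
    def _lesion(self, shape=(4, 4, 1)):
        roi = np.zeros(shape, bool)
        roi[1:3, 1:3, 0] = True
        return Lesion(0, "bone", (0, 0, 0), 4.0, roi)

    def test_identical_images_zero_error(self):
        img = _vol(np.full((4, 4, 1), 900.0))
        res = ev.lesion_metrics([self._lesion()], {"a": img, "gs": img}, "gs")
        assert res[0].relative_error["a"] == 0.0

    def test_sign_and_magnitude_convention(self):
        gs = np.full((4, 4, 1), 100.0)
        gs[1, 1, 0] = 1000.0
        x = np.full((4, 4, 1), 100.0)
        x[1, 1, 0] = 800.0
        res = ev.lesion_metrics([self._lesion()],
                                {"x": _vol(x), "gs": _vol(gs)}, "gs")
        assert res[0].relative_error["x"] == pytest.approx(-0.20)
        assert res[0].abs_percentage_error["x"] == pytest.approx(20.0)

    def test_suv_factor_cancels(self):
        gs = _vol(np.full((4, 4, 1), 1000.0))
        x = _vol(np.full((4, 4, 1), 900.0))
        r1 = ev.lesion_metrics([self._lesion()], {"x": x, "gs": gs}, "gs",
                               suv_factor=1.0)
        r2 = ev.lesion_metrics([self._lesion()], {"x": x, "gs": gs}, "gs",
                               suv_factor=123.4)
        assert r1[0].relative_error["x"] == pytest.approx(
            r2[0].relative_error["x"], rel=1e-12)

    def test_empty_roi_reported_not_raised(self):
        les = Lesion(7, "bone", (0, 0, 0), 1.0, np.zeros((4, 4, 1), bool))
        img = _vol(np.ones((4, 4, 1)))
        res = ev.lesion_metrics([les], {"x": img, "gs": img}, "gs")
        assert res[0].error == "empty ROI"


class TestPairedCompare:
    def test_identical_samples_degenerate(self):
        rep = ev.paired_compare(np.arange(10.0), np.arange(10.0))
        assert rep.degenerate and not rep.significant

    def test_constant_shift_matches_exact_signed_rank(self):
        """n=10, all differences positive: exact two-sided p = 2/2^10."""
        a = np.arange(10.0) + 1.0
        b = np.arange(10.0)
        rep = ev.paired_compare(a, b)
        assert rep.p_value == pytest.approx(2.0 / 2 ** 10)
        assert rep.significant

    def test_requires_five_pairs(self):
        with pytest.raises(ValueError):
            ev.paired_compare([1, 2], [3, 4])


class TestUnpairedCompare:
    def test_identical_groups_not_significant(self):
        rep = ev.unpaired_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert not rep.significant

    def test_disjoint_groups_match_exact_u_distribution(self):
        """Complete separation, n=m=8: U=0 and exact p = 2/C(16,8)."""
        a = np.arange(8.0)
        b = np.arange(8.0) + 100.0
        rep = ev.unpaired_compare(a, b)
        assert rep.statistic in (0.0, 64.0)
        from math import comb
        assert rep.p_value == pytest.approx(2.0 / comb(16, 8))
        assert rep.significant

    def test_single_observation_per_group_powerless(self):
        rep = ev.unpaired_compare([1.0], [2.0])
        assert rep.p_value == pytest.approx(1.0)
        assert not rep.significant


class TestBenjaminiHochberg:
    def test_step_up_all_rejected(self):
        reject, _ = ev.bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_step_up_partial_rejection_hand_case(self):
        # thresholds k/4*0.05 = .0125, .025, .0375, .05 on sorted p
        reject, _ = ev.bh_adjust([0.01, 0.04, 0.03, 0.5], alpha=0.05)
        assert list(reject) == [True, False, False, False]


def test_median_range_format():
    assert ev.median_range([1.0, 2.0, 3.0]) == "2.0 [1.0, 3.0]"
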