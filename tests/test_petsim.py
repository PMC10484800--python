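import numpy as np
import pytest

import petcorr as pc
from petcorr.mumap import MuMap
from petcorr.petsim import _get_projector
from petcorr.volume import ImageVolume


def _vol(arr2d, role, spacing=4.0):
    return ImageVolume(np.asarray(arr2d, dtype=float)[:, :, None],
                       (spacing, spacing, spacing), role=role)


def _mu(arr2d, spacing=4.0, prov="reference"):
    return MuMap(_vol(arr2d, "lac_cm", spacing), prov)


def _disc(n=64, r=20, level=5000.0):
    x, y = np.meshgrid(np.arange(n) - (n - 1) / 2, np.arange(n) - (n - 1) / 2,
                       indexing="ij")
    return (x ** 2 + y ** 2 <= r ** 2) * level


NOISELESS = dict(noise=False, postfilter_fwhm_mm=0.0)


class TestForwardProject:
    def test_zero_mu_gives_pure_line_integrals(self):
        # odd grid: at angle 0 each pixel column lands in exactly one bin
        n = 65
        act = np.zeros((n, n))
        act[32, 10:20] = 1000.0
        cfg = pc.ReconConfig(n_angles=4, subsets=1, mean_true_counts_per_slice=0,
                             **NOISELESS)
        sino = pc.forward_project(_vol(act, "activity_bqml"),
                                  _mu(np.zeros((n, n))), cfg)
        proj = _get_projector((n, n, 1), (4.0, 4.0, 4.0), cfg)
        theta0 = sino.counts[0, 0]
        expected = np.zeros(proj.n_bins)
        center = (proj.n_bins - 1) // 2
        expected[center] = 1000.0 * 10 * 0.4   # 10 voxels of 0.4 cm
        np.testing.assert_allclose(theta0, expected, atol=1e-9)

    def test_uniform_slab_attenuation_closed_form(self):
        # hot voxel behind a 10 cm slab of mu=0.1 along the axis-aligned line
        n = 65
        act = np.zeros((n, n))
        act[32, 32] = 1000.0
        mu = np.zeros((n, n))
        mu[32, 7:32] = 0.1          # 25 voxels * 0.4 cm = 10 cm
        cfg = pc.ReconConfig(n_angles=4, subsets=1, mean_true_counts_per_slice=0,
                             **NOISELESS)
        s_mu = pc.forward_project(_vol(act, "activity_bqml"), _mu(mu), cfg)
        s_0 = pc.forward_project(_vol(act, "activity_bqml"),
                                 _mu(np.zeros((n, n))), cfg)
        center = (s_mu.n_bins - 1) // 2
        ratio = s_mu.counts[0, 0, center] / s_0.counts[0, 0, center]
        assert ratio == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_zero_activity_gives_zero_sinogram(self):
        cfg = pc.ReconConfig(n_angles=4, subsets=1, **NOISELESS)
        sino = pc.forward_project(_vol(np.zeros((16, 16)), "activity_bqml"),
                                  _mu(np.full((16, 16), 0.1)), cfg)
        assert (sino.counts == 0).all()

    def test_count_conservation_without_attenuation(self):
        act = _disc(48, 15, 3000.0)
        cfg = pc.ReconConfig(n_angles=42, subsets=21, mean_true_counts_per_slice=0,
                             **NOISELESS)
        sino = pc.forward_project(_vol(act, "activity_bqml"),
                                  _mu(np.zeros((48, 48))), cfg)
        per_angle = sino.counts[0].sum(axis=1)
        np.testing.assert_allclose(per_angle, act.sum() * 0.4, rtol=1e-12)

    def test_poisson_noise_seeded(self):
        act = _disc(32, 10)
        cfg = lambda s: pc.ReconConfig(n_angles=42, subsets=21, noise=True, seed=s)
        mk = lambda s: pc.forward_project(_vol(act, "activity_bqml"),
                                          _mu(np.zeros((32, 32))), cfg(s)).counts
        np.testing.assert_array_equal(mk(5), mk(5))
        assert (mk(5) != mk(6)).any()


class TestReconstruct:
    def test_uniform_disc_recovery_within_5_percent(self):
        act = _disc(64, 20, 5000.0)
        mu = _mu((act > 0) * 0.096)
        cfg = pc.ReconConfig(**NOISELESS)   # 3 iterations x 21 subsets
        sino = pc.forward_project(_vol(act, "activity_bqml"), mu, cfg)
        rec = pc.reconstruct(sino, mu, cfg)
        inside = act > 0
        assert rec.data[:, :, 0][inside].mean() == pytest.approx(5000.0, rel=0.05)

    def test_osem_one_subset_equals_mlem_oracle(self):
        """OSEM with a single subset must match a plain MLEM loop update-for-update."""
        act = _disc(32, 10, 4000.0)
        mu = _mu((act > 0) * 0.096)
        cfg = pc.ReconConfig(n_angles=42, subsets=1, iterations=4, **NOISELESS)
        sino = pc.forward_project(_vol(act, "activity_bqml"), mu, cfg)
        rec = pc.reconstruct(sino, mu, cfg)

        # independent MLEM loop on the same system matrix
        proj = _get_projector((32, 32, 1), (4.0, 4.0, 4.0), cfg)
        M = proj.full
        atn = np.exp(-(M @ (mu.data[:, :, 0].ravel()))) * sino.scale
        y = sino.counts[0].ravel()
        x = np.ones(32 * 32)
        sens = M.T @ atn
        for _ in range(cfg.iterations):
            fp = atn * (M @ x)
            ratio = np.divide(y, fp, out=np.zeros_like(fp), where=fp > 1e-12)
            x = x / np.maximum(sens, 1e-30) * (M.T @ (atn * ratio))
        np.testing.assert_allclose(rec.data[:, :, 0].ravel(), x, rtol=1e-8)

    def test_empty_sinogram_gives_zero_image(self):
        mu = _mu(np.zeros((32, 32)))
        cfg = pc.ReconConfig(n_angles=42, subsets=21, **NOISELESS)
        sino = pc.forward_project(_vol(np.zeros((32, 32)), "activity_bqml"), mu, cfg)
        rec = pc.reconstruct(sino, mu, cfg)
        assert (rec.data == 0).all()

    def test_output_non_negative(self, subject_noiseless):
        assert subject_noiseless.pet4c.data.min() >= 0.0
        assert subject_noiseless.petref.data.min() >= 0.0

    def test_mismatched_mu_underestimates_bone(self):
        act = _disc(64, 26, 3000.0)
        body = act > 0
        x, y = np.meshgrid(np.arange(64) - 31.5, np.arange(64) - 31.5, indexing="ij")
        bone = ((x + 10) ** 2 + y ** 2 <= 5 ** 2)
        mu4 = body * 0.096
        mur = mu4.copy()
        mur[bone] = 0.15
        cfg = pc.ReconConfig(noise=False)
        sino = pc.forward_project(_vol(act, "activity_bqml"), _mu(mur), cfg)
        rec_mis = pc.reconstruct(sino, _mu(mu4, prov="four_class"), cfg)
        rec_match = pc.reconstruct(sino, _mu(mur), cfg)
        assert rec_mis.data[:, :, 0][bone].mean() < rec_match.data[:, :, 0][bone].mean()

    def test_mismatch_bias_monotone_in_bone_lac(self):
        act = _disc(64, 26, 3000.0)
        body = act > 0
        x, y = np.meshgrid(np.arange(64) - 31.5, np.arange(64) - 31.5, indexing="ij")
        bone = ((x + 10) ** 2 + y ** 2 <= 5 ** 2)
        mu4 = body * 0.096
        cfg = pc.ReconConfig(noise=False)
        means = []
        for lac in (0.11, 0.14, 0.17):
            mur = mu4.copy()
            mur[bone] = lac
            sino = pc.forward_project(_vol(act, "activity_bqml"), _mu(mur), cfg)
            rec = pc.reconstruct(sino, _mu(mu4, prov="four_class"), cfg)
            means.append(rec.data[:, :, 0][bone].mean())
        assert means[0] > means[1] > means[2]


class TestSimulatePair:
    def test_identical_mu_maps_give_identical_images(self, phantom_seed1):
        ph = phantom_seed1
        mu4c = pc.four_class_mumap(ph.dixon_ip, ph.dixon_op, ph.body_mask)
        cfg = pc.ReconConfig(noise=False)
        a, b = pc.simulate_pet_pair(ph, mu4c, pc.MuMap(mu4c.volume, "reference"),
                                    cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_bone_mean_lower_in_pet4c(self, subject_noiseless):
        s = subject_noiseless
        bone = s.phantom.labels.data == 3
        assert s.pet4c.data[bone].mean() < s.petref.data[bone].mean()

    def test_noiseless_determinism(self, phantom_seed1):
        ph = phantom_seed1
        mu4c = pc.four_class_mumap(ph.dixon_ip, ph.dixon_op, ph.body_mask)
        muref = pc.insert_bone(mu4c, pc.hu_to_lac(ph.ct), ph.pelvic_mask)
        cfg = pc.ReconConfig(noise=False, seed=0)
        a1, _ = pc.simulate_pet_pair(ph, mu4c, muref, cfg)
        a2, _ = pc.simulate_pet_pair(ph, mu4c, muref,
                                     pc.ReconConfig(noise=False, seed=99))
        np.testing.assert_array_equal(a1.data, a2.data)


class TestConfigValidation:
    def test_subsets_must_divide_angles(self):
        with pytest.raises(ValueError):
            pc.ReconConfig(n_angles=100, subsets=21)

    def test_grid_mismatch_raises(self):
        act = _vol(np.zeros((16, 16)), "activity_bqml")
        mu = _mu(np.zeros((17, 17)))
        with pytest.raises(Exception):
            pc.forward_project(act, mu, pc.ReconConfig(n_angles=4, subsets=1))
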