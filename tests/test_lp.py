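"""Local-projection PVC: segmentation rules, VOI construction, tissue
projections, activity fitting, substitution, the full pipeline and the
PSF calibration."""


import numpy as np
import pytest

import lppvc
from lppvc import (ImageVolume, ReconConfig, Sinogram, StageError,
                   calibrate_fwhm, compute_tissue_projections,
                   define_local_voi, estimate_outside_background,
                   fit_lp_activities, forward_project, osem, run_lp_pvc,
                   segment_ct_threshold, segment_pet_halfmax, shift_volume,
                   substitute_voi)
from lppvc.lp import LocalVOI, TissueProjectionSet
from lppvc.volume import centered_grid


def _volume(values, voxel=(2.0, 2.0, 2.0), role="activity"):
    return ImageVolume(values, voxel, centered_grid(values.shape, voxel), role)


class TestSegmentation:
    def test_ct_threshold_selects_calcification(self):
        hu = np.full((20, 20, 10), 40.0)
        hu[8:12, 8:12, 4:6] = 600.0
        mask = segment_ct_threshold(_volume(hu, role="hu"), np.ones_like(hu, bool), 110.0)
        assert np.array_equal(mask, hu > 110)

    def test_ct_threshold_empty_errors(self):
        hu = np.full((10, 10, 6), 50.0)
        with pytest.raises(ValueError, match="no calcified"):
            segment_ct_threshold(_volume(hu, role="hu"), np.ones_like(hu, bool))

    def test_ct_threshold_keeps_largest_component(self):
        hu = np.full((24, 24, 8), 0.0)
        hu[2:4, 2:7, 2] = 300.0        # 10-voxel component
        hu[18:19, 18:21, 5] = 300.0    # 3-voxel component
        mask = segment_ct_threshold(_volume(hu, role="hu"), np.ones_like(hu, bool))
        assert mask.sum() == 10 and mask[2, 2, 2]

    def test_pet_halfmax_threshold_value(self):
        """Max 23.8 over background 4.8 thresholds at 14.3 kBq/mL."""
        img = np.full((20, 20, 10), 4.8)
        img[10, 10, 5] = 23.8
        img[10, 11, 5] = 14.3   # exactly at threshold: included
        img[10, 12, 5] = 14.2   # just below: excluded
        mask = segment_pet_halfmax(_volume(img), np.ones_like(img, bool), 4.8)
        assert mask[10, 10, 5] and mask[10, 11, 5] and not mask[10, 12, 5]

    def test_pet_halfmax_zero_background(self):
        img = np.zeros((16, 16, 8))
        img[8, 8, 4] = 10.0
        img[8, 9, 4] = 5.0
        mask = segment_pet_halfmax(_volume(img), np.ones_like(img, bool), 0.0)
        assert mask[8, 8, 4] and mask[8, 9, 4] and mask.sum() == 2

    def test_pet_halfmax_uniform_errors(self):
        img = np.full((16, 16, 8), 4.8)
        with pytest.raises(ValueError, match="not distinguishable"):
            segment_pet_halfmax(_volume(img), np.ones_like(img, bool), 4.8)


class TestLocalVOI:
    def _lesion(self, shape=(40, 40, 24), r=6.5):
        X, Y, Z = np.meshgrid(*(( np.arange(n) - (n - 1) / 2) * 2.0 for n in shape), indexing="ij")
        return (X**2 + Y**2 + Z**2) <= r**2, _volume(np.zeros(shape))

    def test_margin_builds_background_shell(self):
        mask, grid = self._lesion()
        voi = define_local_voi(mask, grid, margin_mm=12.0)
        assert voi.J == 2
        assert np.array_equal(voi.tissue_mask(1), mask)
        shell = voi.tissue_mask(2)
        assert shell.any() and not (shell & mask).any()

    def test_zero_margin_is_lesion_only(self):
        mask, grid = self._lesion()
        voi = define_local_voi(mask, grid, margin_mm=0.0)
        assert voi.J == 1 and np.array_equal(voi.voi_mask, mask)

    def test_extra_tissue_partitions(self):
        mask, grid = self._lesion()
        extra = np.zeros_like(mask)
        extra[26:29, 18:22, 10:14] = True
        voi = define_local_voi(mask, grid, margin_mm=12.0, extra_tissues=[extra])
        assert voi.J == 3
        labels = voi.tissue_label
        assert set(np.unique(labels)) == {0, 1, 2, 3}
        # tissues are disjoint by construction of a single label volume
        assert (labels[mask] == 1).all()

    def test_voi_touching_boundary_errors(self):
        mask, grid = self._lesion()
        with pytest.raises(ValueError, match="boundary"):
            define_local_voi(mask, grid, margin_mm=40.0)

    def test_labels_must_partition(self):
        bad = np.zeros((8, 8, 8), dtype=np.int32)
        bad[2, 2, 2] = 3  # label 3 without 1 and 2
        with pytest.raises(ValueError, match="partition"):
            LocalVOI(bad, 3, (2.0, 2.0, 2.0))


class TestTissueProjections:
    def test_single_voxel_mass(self, small_model):
        """An unattenuated single-voxel tissue projects to a total of
        count_scale x voxel volume."""
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[16, 16, 4] = 1
        voi = LocalVOI(labels, 1, small_model.voxel_size_mm)
        P = compute_tissue_projections(voi, small_model)
        expected = small_model.count_scale * np.prod(small_model.voxel_size_mm)
        assert P.projections[0].sum() == pytest.approx(expected, rel=0.005)

    def test_sum_equals_voi_projection(self, small_model):
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[14:18, 14:18, 3:6] = 2
        labels[15:17, 15:17, 4] = 1
        voi = LocalVOI(labels, 2, small_model.voxel_size_mm)
        P = compute_tissue_projections(voi, small_model)
        whole = forward_project(voi.voi_mask.astype(float), small_model,
                                include_scatter=False).values
        assert np.abs(P.projections.sum(axis=0) - whole).max() < 1e-8
        assert np.all(P.projections[:, ~P.support] == 0)


class TestFit:
    def _setup(self, small_model):
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[12:20, 12:20, 3:6] = 2
        labels[14:18, 14:18, 4] = 1
        voi = LocalVOI(labels, 2, small_model.voxel_size_mm)
        P = compute_tissue_projections(voi, small_model)
        rng = np.random.default_rng(4)
        outside = rng.random(small_model.grid_shape) * 2.0
        outside[voi.voi_mask] = 0.0
        g = forward_project(outside, small_model, include_scatter=False)
        return voi, P, g

    def test_exact_linear_recovery(self, small_model):
        """Noise-free counts built as 3 P1 + 1 P2 + g recover A=(3,1)."""
        voi, P, g = self._setup(small_model)
        y = Sinogram(3.0 * P.projections[0] + 1.0 * P.projections[1] + g.values,
                     small_model.geometry)
        fit = fit_lp_activities(y, P, g)
        assert fit.activities == pytest.approx([3.0, 1.0], abs=1e-6)
        assert fit.residual_norm < 1e-6

    def test_single_tissue_closed_form(self, small_model):
        """J=1 weighted least squares equals the scalar formula
        sum(w (y-g) P) / sum(w P^2)."""
        voi, P, g = self._setup(small_model)
        labels = np.where(voi.tissue_label > 0, 1, 0).astype(np.int32)
        voi1 = LocalVOI(labels, 1, small_model.voxel_size_mm)
        P1 = compute_tissue_projections(voi1, small_model)
        rng = np.random.default_rng(5)
        y = Sinogram(2.5 * P1.projections[0] + g.values + rng.random(g.values.shape),
                     small_model.geometry)
        fit = fit_lp_activities(y, P1, g, nonneg=False, n_reweight=0)
        s = P1.support
        w = 1.0 / np.maximum(g.values[s], 1.0)
        p = P1.projections[0][s]
        oracle = (w * (y.values[s] - g.values[s]) * p).sum() / (w * p * p).sum()
        assert fit.activities[0] == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_projections_rejected(self, small_model):
        voi, P, g = self._setup(small_model)
        dup = TissueProjectionSet(np.stack([P.projections[0], P.projections[0] * 2.0]),
                                  P.support, voi, P.model_fwhm_mm)
        y = Sinogram(P.projections[0] + g.values, small_model.geometry)
        with pytest.raises(ValueError, match="degenerate"):
            fit_lp_activities(y, dup, g)

    def test_pure_background_voi_fits_zero(self, small_model):
        """A VOI placed where the object has no activity fits ~0 while the
        outside emission is fully explained by g_out."""
        voi, P, g = self._setup(small_model)
        y = Sinogram(g.values.copy(), small_model.geometry)  # outside emission only
        fit = fit_lp_activities(y, P, g)
        assert np.all(fit.activities < 1e-8)
        assert np.all(g.values >= 0)


class TestSubstitute:
    def test_piecewise_constant_and_outside_untouched(self, small_model):
        rng = np.random.default_rng(6)
        img = _volume(rng.random(small_model.grid_shape) * 5)
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[12:20, 12:20, 3:6] = 2
        labels[14:18, 14:18, 4] = 1
        voi = LocalVOI(labels, 2, small_model.voxel_size_mm)
        from lppvc.lp import LPFit
        fit = LPFit(activities=np.array([5.0, 1.25]), g_out=None, model_counts=None,
                    residual_norm=0.0, activity_covariance=np.eye(2), support=None)
        out = substitute_voi(img, voi, fit)
        assert set(np.unique(out.values[voi.voi_mask])) == {1.25, 5.0}
        outside = ~voi.voi_mask
        assert np.array_equal(out.values[outside], img.values[outside])


class TestOutsideBackground:
    def test_zero_image_zero_scatter(self, small_model):
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[14:18, 14:18, 3:5] = 1
        voi = LocalVOI(labels, 1, small_model.voxel_size_mm)
        img = _volume(np.zeros(small_model.grid_shape))
        g = estimate_outside_background(img, voi, small_model)
        assert np.all(g.values == 0)


class TestPipeline:
    def test_pvc_image_improves_small_sphere_lbr(self, tiny_nema):
        """Re-reconstruction from LP activities raises LBR_max of the
        small spheres over the uncorrected OSEM image.  Simulated at 8-mm
        resolution, where 10-13 mm spheres suffer strong partial-volume
        losses, and noise-free so the uncorrected maximum is resolution-
        not noise-limited."""
        sim = lppvc.simulate_acquisition(tiny_nema.activity, tiny_nema.mu,
                                         psf_fwhm_mm=8.0, scatter_fraction=0.2,
                                         target_total_counts=2e5, n_angles=60, noise=False)
        img = osem(sim.counts, sim.model, ReconConfig(5, 21))
        bgmask = lppvc.background_voi_mask(
            tiny_nema.body_mask, [tiny_nema.lesion_mask(i) for i in tiny_nema.intended],
            tiny_nema.activity.voxel_size_mm, diameter_mm=10.0, clearance_mm=12.0,
            edge_clearance_mm=4.0, target_depth_mm=15.0)
        for lid in (1, 2):  # 10 and 13 mm spheres
            res = run_lp_pvc(sim.counts, img, sim.model,
                             lesion_mask=tiny_nema.lesion_mask(lid),
                             margin_mm=6.0, noise=False)
            lbr_before = lppvc.lbr_max(img, tiny_nema.lesion_mask(lid), bgmask)
            lbr_after = lppvc.lbr_max(res.pvc_image, tiny_nema.lesion_mask(lid), bgmask)
            assert lbr_after > lbr_before
            out = ~res.voi.voi_mask
            assert np.array_equal(res.substituted_image.values[out], img.values[out])

    def test_zero_lesion_phantom_no_false_enhancement(self):
        """A lesion-free phantom yields a PVC image close to the input:
        no activity is invented by the correction."""
        ph = lppvc.build_carotid_section(plaque_volume_mm3=0.0, grid_shape=(48, 48, 24))
        sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=4.0,
                                         scatter_fraction=0.2, target_total_counts=3e5,
                                         n_angles=60, noise=False)
        img = osem(sim.counts, sim.model, ReconConfig(5, 21))
        fake = np.zeros(ph.activity.shape, dtype=bool)
        fake[20:24, 20:24, 10:13] = True
        res = run_lp_pvc(sim.counts, img, sim.model, lesion_mask=fake,
                         margin_mm=8.0, noise=False)
        inb = ph.body_mask
        assert np.abs(res.pvc_image.values[inb] - img.values[inb]).mean() < 0.05
        # no contrast invented: the "lesion" tissue does not rise above its
        # local background, and the VOI LBR is essentially unchanged
        a = res.lp_fit.activities
        assert a[0] <= 1.1 * a[1]
        lbr_img = lppvc.lbr_max(img, fake, ph.body_mask & ~fake)
        lbr_pvc = lppvc.lbr_max(res.pvc_image, fake, ph.body_mask & ~fake)
        assert abs(lppvc.delta_lbr(lbr_pvc, lbr_img)) < 15.0

    def test_stage_tagged_errors(self, tiny_nema, tiny_nema_recon, tiny_nema_sim):
        with pytest.raises(StageError, match=r"\[segment\]"):
            run_lp_pvc(tiny_nema_sim.counts, tiny_nema_recon, tiny_nema_sim.model,
                       segmentation="pet", search_region=np.ones(tiny_nema_recon.shape, bool),
                       background_mean=1e9, seed=0)

    def test_exact_recovery_all_j(self, small_model):
        """Noise-free matched-model data with exact segmentation recover
        the true tissue activities for J = 1, 2, 3."""
        rng = np.random.default_rng(8)
        base = np.zeros(small_model.grid_shape)
        base[4:28, 4:28, 1:7] = 2.0  # uniform body
        labels = np.zeros(small_model.grid_shape, dtype=np.int32)
        labels[12:20, 12:20, 3:6] = 2
        labels[14:18, 14:18, 4] = 1
        labels[12:14, 12:14, 3] = 3
        for J, truth in ((1, [9.0]), (2, [9.0, 2.0]), (3, [9.0, 2.0, 5.0])):
            lab = np.where(np.isin(labels, np.arange(1, J + 1)), labels, 0).astype(np.int32)
            voi = LocalVOI(lab, J, small_model.voxel_size_mm)
            act = base.copy()
            for j, a in enumerate(truth, start=1):
                act[lab == j] = a
            counts = forward_project(act, small_model, include_scatter=False)
            P = compute_tissue_projections(voi, small_model)
            outside = act.copy()
            outside[voi.voi_mask] = 0.0
            g = forward_project(outside, small_model, include_scatter=False)
            fit = fit_lp_activities(counts, P, g)
            assert fit.activities == pytest.approx(truth, abs=1e-6)


class TestSubvoxelCaveat:
    def test_lp_underestimates_subvoxel_lesion_with_pet_segmentation(self, tiny_thorax):
        """For a lesion far below the sampling limit, PET-based
        segmentation overestimates the volume and the LP activity falls
        short of the true ratio."""
        ph = tiny_thorax
        sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=8.0,
                                         scatter_fraction=0.2, target_total_counts=1e6,
                                         n_angles=60, noise=False)
        img = osem(sim.counts, sim.model, ReconConfig(5, 21, postfilter_fwhm_mm=5.0))
        lid = [k for k, m in ph.intended.items() if m["volume_mm3"] == 18.0][0]
        ctr = np.array([np.where(ph.lesion_mask(lid))[a].mean() for a in range(3)]).round().astype(int)
        search = np.zeros(ph.activity.shape, bool)
        search[tuple(slice(max(c - 5, 0), c + 6) for c in ctr)] = True
        seg = segment_pet_halfmax(img, search, 4.0)
        voi = define_local_voi(seg, img, margin_mm=6.0)
        P = compute_tissue_projections(voi, sim.model)
        g = estimate_outside_background(img, voi, sim.model)
        fit = fit_lp_activities(sim.counts, P, g)
        assert fit.lesion_activity / 4.0 < 70.0


class TestCalibration:
    @pytest.mark.parametrize("true_fwhm", [4.0, 8.0])
    def test_recovers_blur_within_half_mm(self, calibration_phantom, true_fwhm):
        ph = calibration_phantom
        sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=true_fwhm,
                                         scatter_fraction=0.2, target_total_counts=5e5,
                                         n_angles=60, noise=False)
        img = osem(sim.counts, sim.model, ReconConfig(5, 21))
        f = calibrate_fwhm(sim.counts, img, sim.model, ph.lesion_mask(1),
                           true_ratio=4.95, background_mean=4.8, bounds=(1.5, 14.0))
        assert f == pytest.approx(true_fwhm, abs=0.5)

    def test_bounds_excluding_truth_error(self, calibration_phantom):
        ph = calibration_phantom
        sim = lppvc.simulate_acquisition(ph.activity, ph.mu, psf_fwhm_mm=8.0,
                                         scatter_fraction=0.2, target_total_counts=5e5,
                                         n_angles=60, noise=False)
        img = osem(sim.counts, sim.model, ReconConfig(5, 21))
        with pytest.raises(ValueError, match="bound"):
            calibrate_fwhm(sim.counts, img, sim.model, ph.lesion_mask(1),
                           true_ratio=4.95, background_mean=4.8, bounds=(1.5, 4.0))


def test_shift_volume_roundtrip(tiny_nema_recon):
    shifted = shift_volume(tiny_nema_recon, (2, -1, 0))
    back = shift_volume(shifted, (-2, 1, 0))
    inner = (slice(3, -3),) * 3
    assert np.array_equal(back.values[inner], tiny_nema_recon.values[inner])
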