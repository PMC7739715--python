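import numpy as np
import pytest

from adipoquant.mriseg import (
    BoundaryCurve,
    body_mask,
    brute_force_circular_path,
    correct_bias,
    detect_sat_boundaries,
    kmeans_threshold,
    mask_inside_curve,
    mask_to_mass,
    min_circular_path,
    reroll_mask,
    restrict_to_slices,
    sat_mask_from_boundaries,
    segment_depots,
    segment_internal_fat,
    select_slices,
    unroll_slice,
)
from adipoquant.phantoms import LIVER, SAT, INTERNAL_FAT, PhantomSpec, generate_phantom
from adipoquant.volume import ImageVolume


def _dice(a, b):
    return 2.0 * (a & b).sum() / max(a.sum() + b.sum(), 1)


def _disc_volume(n=64, r=20, value=100.0, slices=2):
    c = (n - 1) / 2
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    disc = np.hypot(ii - c, jj - c) <= r
    vox = np.where(disc, value, 0.0)
    return ImageVolume(np.repeat(vox[:, :, None], slices, axis=2), modality="MRI"), disc


class TestBiasCorrection:
    def test_bias_free_phantom_passes_through(self, noiseless_annulus):
        _, (mri, _, _) = noiseless_annulus
        out = correct_bias(mri)
        fg = mri.voxels > 100
        rms = np.sqrt(np.mean((out.voxels[fg] - mri.voxels[fg]) ** 2))
        assert rms / mri.voxels[fg].mean() < 0.005

    def test_known_degree2_field_is_removed(self):
        spec = PhantomSpec(n_slices=2, internal_fat_fraction=0.15,
                           bias_amplitude=0.0, noise_sd=0.0, seed=3)
        mri, _, truth = generate_phantom(spec, "abdomen")
        n = mri.voxels.shape[0]
        c = (n - 1) / 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        xn, yn = (ii - c) / c, (jj - c) / c
        field = 1.0 + 0.2 * (0.8 * xn + 0.3 * yn**2 - 0.5 * xn * yn)
        biased = mri.with_voxels(mri.voxels * field[:, :, None])
        corrected = correct_bias(biased)
        fg = truth.label_volume.voxels > 0
        ratio = corrected.voxels[fg] / mri.voxels[fg]
        assert ratio.std() / ratio.mean() < 0.02

    def test_constant_image_unchanged(self):
        v = ImageVolume(np.full((16, 16, 1), 7.0), modality="MRI")
        assert np.allclose(correct_bias(v).voxels, 7.0)

    def test_non_mri_rejected(self):
        with pytest.raises(ValueError, match="MRI"):
            correct_bias(ImageVolume(np.zeros((4, 4, 1)), modality="CT"))


class TestBodyMask:
    def test_disc_phantom_recovered(self):
        vol, disc = _disc_volume()
        m = body_mask(vol)
        assert _dice(m[:, :, 0], disc) > 0.99

    def test_detached_speck_excluded(self):
        vol, disc = _disc_volume()
        vox = vol.voxels.copy()
        vox[2:4, 2:4, :] = 100.0  # small detached speck
        m = body_mask(vol.with_voxels(vox))
        assert not m[2:4, 2:4, :].any()
        assert _dice(m[:, :, 0], disc) > 0.99

    def test_annulus_hole_filled(self):
        n, c = 64, 31.5
        ii, jj = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        r = np.hypot(ii - c, jj - c)
        ring = (r > 10) & (r <= 20)
        vol = ImageVolume(np.where(ring, 100.0, 0.0)[:, :, None], modality="MRI")
        m = body_mask(vol)[:, :, 0]
        assert m[(r <= 10)].all()  # hole filled
        assert not m[r > 21].any()

    def test_empty_slice_warns_not_errors(self):
        vol, _ = _disc_volume()
        vox = vol.voxels.copy()
        vox[:, :, 1] = 0.0
        with pytest.warns(RuntimeWarning, match="no foreground"):
            m = body_mask(vol.with_voxels(vox))
        assert not m[:, :, 1].any() and m[:, :, 0].any()


class TestUnroll:
    def test_symmetric_smooth_annulus_columns_identical(self):
        # a radially smooth ring: interpolation error is the only source of
        # column-to-column variation (a hard pixelated edge would add
        # quantization noise unrelated to the resampling itself)
        n = 201
        c = (n - 1) / 2
        ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r = np.hypot(ii - c, jj - c)
        sl = 1000.0 * np.exp(-((r - 70.0) ** 2) / (2 * 8.0**2))
        polar = unroll_slice(sl, (c, c), n_angles=180, pixel_size_mm=1.0)
        col_rms = polar.samples.std(axis=0).max()
        assert col_rms < 0.01 * polar.samples.max()

    def test_unroll_reroll_roundtrip_dice(self, noiseless_annulus):
        spec, (mri, _, truth) = noiseless_annulus
        sat = truth.mask(SAT)[:, :, 0]
        c = (sat.shape[0] - 1) / 2
        polar = unroll_slice(sat.astype(float), (c, c), n_angles=360,
                             pixel_size_mm=spec.pixel_size_mm)
        back = reroll_mask(polar, polar.samples > 0.5)
        assert _dice(back, sat) >= 0.98

    def test_boundary_stable_under_angle_doubling(self, noiseless_annulus):
        spec, (mri, _, _) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        radii = {}
        for n_angles in (180, 360):
            polar = unroll_slice(sl, (c, c), n_angles=n_angles,
                                 pixel_size_mm=spec.pixel_size_mm)
            _, inner = detect_sat_boundaries(polar, delta=2)
            radii[n_angles] = inner.radius_per_angle
        diff = np.abs(radii[360][::2] - radii[180])
        # integer radii: at most one quantization step anywhere, <0.5 on average
        assert diff.max() <= 1
        assert diff.mean() < 0.5

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            unroll_slice(np.zeros((10, 10)), (20, 5))


class TestBoundaries:
    def test_noiseless_annulus_within_one_sample(self, noiseless_annulus):
        spec, (mri, _, _) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        outer, inner = detect_sat_boundaries(polar, delta=2)
        assert np.abs(inner.radius_per_angle - 80.0 / polar.radial_step_mm).max() <= 1.0
        assert np.abs(outer.radius_per_angle - 95.0 / polar.radial_step_mm).max() <= 1.0

    def test_delta_zero_on_symmetric_annulus_is_constant(self, noiseless_annulus):
        spec, (mri, _, _) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        _, inner = detect_sat_boundaries(polar, delta=0)
        assert np.ptp(inner.radius_per_angle) == 0

    def test_curves_satisfy_closure_invariant(self, default_abdomen):
        spec, (mri, _, _) = default_abdomen
        sl = mri.slice2d(3)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        outer, inner = detect_sat_boundaries(polar, delta=2)
        assert abs(int(inner.radius_per_angle[0]) - int(inner.radius_per_angle[-1])) <= 2
        jumps = np.abs(np.diff(inner.radius_per_angle))
        assert jumps.max() <= 2

    def test_closure_violation_rejected(self):
        with pytest.raises(ValueError, match="closure"):
            BoundaryCurve(np.array([0, 1, 2, 9]), smoothness_delta=2)

    def test_infeasible_grid_raises_naming_constraint(self):
        cost = np.full((6, 4), 1e18)
        with pytest.raises(ValueError, match="delta"):
            min_circular_path(cost, 1)


class TestCircularPathOracle:
    @pytest.mark.parametrize("delta", [0, 1, 2])
    def test_dp_equals_brute_force_on_random_grids(self, delta):
        rng = np.random.default_rng(delta)
        for _ in range(10):
            cost = rng.uniform(-1.0, 1.0, size=(8, 6))
            path_dp, cost_dp = min_circular_path(cost, delta)
            path_bf, cost_bf = brute_force_circular_path(cost, delta)
            assert cost_dp == pytest.approx(cost_bf, abs=1e-12)
            # the DP path itself is feasible and achieves the optimum
            total = cost[np.arange(8), path_dp].sum()
            assert total == pytest.approx(cost_bf, abs=1e-12)
            wrap = np.abs(np.diff(np.append(path_dp, path_dp[0])))
            assert wrap.max() <= delta


class TestSatMask:
    def test_exact_curves_give_high_dice_vs_truth(self, noiseless_annulus):
        spec, (mri, _, truth) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        outer, inner = detect_sat_boundaries(polar, delta=2)
        mask = sat_mask_from_boundaries(outer, inner, polar)
        assert _dice(mask, truth.mask(SAT)[:, :, 0]) >= 0.97

    def test_thin_ring_area_matches_geometry(self, noiseless_annulus):
        spec, (mri, _, _) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        r0 = 120  # samples; one radial sample is half an in-plane pixel
        for width, tol in ((1, 0.20), (2, 0.10)):
            outer = BoundaryCurve(np.full(polar.n_angles, r0), 0)
            inner = BoundaryCurve(np.full(polar.n_angles, r0 - width), 0)
            mask = sat_mask_from_boundaries(outer, inner, polar)
            area_mm2 = mask.sum() * spec.pixel_size_mm**2
            r_mid_mm = (r0 - width / 2) * polar.radial_step_mm
            expected = 2 * np.pi * r_mid_mm * width * polar.radial_step_mm
            assert area_mm2 == pytest.approx(expected, rel=tol)

    def test_crossing_curves_rejected(self, noiseless_annulus):
        spec, (mri, _, _) = noiseless_annulus
        sl = mri.slice2d(0)
        c = (sl.shape[0] - 1) / 2
        polar = unroll_slice(sl, (c, c), pixel_size_mm=spec.pixel_size_mm)
        a = BoundaryCurve(np.full(polar.n_angles, 50), 0)
        b = BoundaryCurve(np.full(polar.n_angles, 60), 0)
        with pytest.raises(ValueError, match="strictly inside"):
            sat_mask_from_boundaries(a, b, polar)  # outer below inner


class TestKmeansThreshold:
    def test_five_distinct_clusters(self):
        vals = np.repeat([10.0, 20.0, 30.0, 40.0, 50.0], 100)
        th = kmeans_threshold(vals, seed=0)
        assert 30.0 < th < 40.0  # separates the upper two clusters
        th_mid = kmeans_threshold(vals, seed=0, interpretation="median_center")
        assert th_mid == pytest.approx(30.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(100, 10, 800), rng.normal(300, 15, 200)])
        th = kmeans_threshold(vals, seed=2)
        th_shift = kmeans_threshold(vals + 55.0, seed=2)
        assert th_shift == pytest.approx(th + 55.0, abs=1e-6)

    def test_bimodal_separation_in_at_least_95_of_100_draws(self):
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            muscle = rng.normal(100, 10, 1600)
            fat = rng.normal(300, 15, 400)
            th = kmeans_threshold(np.concatenate([muscle, fat]), seed=seed)
            if np.percentile(muscle, 99) < th < np.percentile(fat, 1):
                ok += 1
        assert ok >= 95

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kmeans_threshold(np.repeat([1.0, 2.0], 50), k=5)


class TestInternalFat:
    def test_perfect_threshold_recovers_truth(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        labels = truth.label_volume.voxels
        internal = labels >= 2  # muscle + fat + organs
        fat = segment_internal_fat(mri.voxels, internal, 700.0,
                                   [truth.mask(LIVER)])
        assert _dice(fat, truth.mask(INTERNAL_FAT)) >= 0.95

    def test_threshold_above_max_gives_empty(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        internal = truth.label_volume.voxels >= 2
        assert segment_internal_fat(mri.voxels, internal, mri.voxels.max() + 1, []).sum() == 0

    def test_full_exclusion_gives_empty(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        internal = truth.label_volume.voxels >= 2
        assert segment_internal_fat(mri.voxels, internal, 700.0, [internal]).sum() == 0

    def test_overlapping_sat_rejected(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        internal = truth.label_volume.voxels >= 2
        with pytest.raises(ValueError, match="overlaps"):
            segment_internal_fat(mri.voxels, internal, 700.0, [], sat_mask=internal)


class TestSliceSelection:
    def test_visceral_rule_on_toy_indices(self):
        rng = select_slices(12, {"th11_th12_disc": 3, "iliac_crest": 10}, "visceral")
        assert rng == (3, 9)

    def test_inverted_landmarks_rejected(self):
        with pytest.raises(ValueError, match="below"):
            select_slices(12, {"th11_th12_disc": 8, "iliac_crest": 3}, "visceral")

    def test_missing_landmark_named(self):
        with pytest.raises(ValueError, match="iliac_crest"):
            select_slices(12, {"th11_th12_disc": 3}, "visceral")

    def test_n_slices_analyzed_count(self):
        rng = select_slices(20, {"gluteal_lower": 2, "patella": 17}, "femoral_sat")
        mask = np.zeros((4, 4, 20), dtype=bool)
        mask[1, 1, 5] = True
        dm = restrict_to_slices(mask, rng, "femoral_sat")
        assert dm.n_slices_analyzed == rng[1] - rng[0] + 1 == 15


class TestMassConversion:
    def test_empty_mask_is_zero(self):
        m = mask_to_mass(np.zeros((4, 4, 2), dtype=bool), (1.1719, 1.1719, 7.2))
        assert m.mass_kg == 0.0

    def test_hand_arithmetic_100k_voxels(self):
        mask = np.zeros((500, 500, 1), dtype=bool)
        mask.ravel()[:100_000] = True
        m = mask_to_mass(mask, (1.1719, 1.1719, 7.2))
        # voxel volume 1.1719^2 * 7.2 = 9.888 mm^3
        assert m.volume_L == pytest.approx(0.9888, abs=5e-4)
        assert m.mass_kg == pytest.approx(0.8899, abs=5e-4)
        assert m.mass_kg == pytest.approx(m.volume_L * 0.9, rel=1e-15)

    def test_mass_linear_in_slice_pitch(self):
        mask = np.ones((10, 10, 2), dtype=bool)
        m1 = mask_to_mass(mask, (1.0, 1.0, 7.2))
        m2 = mask_to_mass(mask, (1.0, 1.0, 14.4))
        assert m2.mass_kg == pytest.approx(2 * m1.mass_kg, rel=1e-12)


class TestEndToEnd:
    def test_noisy_abdomen_masses_within_5pct(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        res = segment_depots(mri, truth.landmarks, region="abdomen",
                             liver_mask=truth.mask(LIVER), seed=0)
        for depot in ("abdominal_sat", "visceral"):
            rec = res.masses[depot].mass_kg
            tru = truth.depot_masses_kg[depot]
            assert abs(rec / tru - 1) < 0.05, depot

    def test_depot_masks_disjoint(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        res = segment_depots(mri, truth.landmarks, region="abdomen",
                             liver_mask=truth.mask(LIVER), seed=0)
        overlap = res.depot_masks["abdominal_sat"].mask & res.depot_masks["visceral"].mask
        assert not overlap.any()

    def test_global_intensity_scaling_invariance(self, default_abdomen):
        spec, (mri, _, truth) = default_abdomen
        res1 = segment_depots(mri, truth.landmarks, region="abdomen",
                              liver_mask=truth.mask(LIVER), seed=0)
        scaled = mri.with_voxels(mri.voxels * 3.7)
        res2 = segment_depots(scaled, truth.landmarks, region="abdomen",
                              liver_mask=truth.mask(LIVER), seed=0)
        for depot in res1.masses:
            assert res2.masses[depot].mass_kg == pytest.approx(
                res1.masses[depot].mass_kg, rel=0.01
            )

    def test_thigh_phantom_segments_all_depots(self):
        spec = PhantomSpec(n_slices=4, body_radius_mm=90.0,
                           sat_thickness_mm=(12.0, 3.0), seed=4)
        mri, _, truth = generate_phantom(spec, "thigh")
        res = segment_depots(mri, truth.landmarks, region="thigh",
                             marrow_mask=truth.mask(5), seed=0)
        assert set(res.masses) == {"femoral_sat", "inter_muscular", "bone_marrow"}
        assert res.masses["bone_marrow"].mass_kg == pytest.approx(
            truth.depot_masses_kg["bone_marrow"], rel=1e-12
        )
        assert abs(res.masses["femoral_sat"].mass_kg
                   / truth.depot_masses_kg["femoral_sat"] - 1) < 0.08
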