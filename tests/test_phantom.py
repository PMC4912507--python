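"""Phantom generation: tissue values, lesion geometry, derived anatomies."""

import numpy as np
import pytest

from cardiacpvc import phantom as ph
from cardiacpvc.image import Image
from cardiacpvc.phantom import (ConfigurationError, GeometryError, LesionSpec,
                                PhantomParams, build_phantom, derive_hrct,
                                derive_mr, make_anisotropic, mismatch_phantom,
                                random_shift_vectors, region_masks,
                                respiratory_states, shift_image,
                                threshold_region_mask)


class TestBuildPhantom:
    def test_tissue_activities(self, desk_phantom):
        act = desk_phantom.activity_true.data
        lab = desk_phantom.label_map.data
        assert act[lab == ph.LV_MYO].mean() == pytest.approx(18.0)
        assert act[lab == ph.RV_MYO].mean() == pytest.approx(12.0)
        assert act[lab == ph.BLOOD].mean() == pytest.approx(5.5)
        assert act[lab == ph.LUNG].mean() == pytest.approx(0.9)
        assert act[lab == ph.LIVER].mean() == pytest.approx(6.5)
        assert act[desk_phantom.masks["L1"]].mean() == pytest.approx(8.0)

    def test_transmural_lesion_is_cold(self, desk_phantom):
        assert np.all(desk_phantom.activity_true.data[desk_phantom.masks["L2"]] == 0.0)

    def test_zero_activity_phantom(self):
        params = PhantomParams.desk()
        params.activities = {k: 0.0 for k in params.activities}
        z = build_phantom(params)
        assert np.all(z.activity_true.data == 0.0)
        ref = build_phantom(PhantomParams.desk())
        for name in z.masks:
            assert np.array_equal(z.masks[name], ref.masks[name])

    def test_lesion_volumes(self, heart_fov_phantom):
        # non-transmural lesion about 3 ml, transmural 1.5 ml
        assert heart_fov_phantom.lesion_volume_ml("L1") == pytest.approx(3.0, rel=0.10)
        assert heart_fov_phantom.lesion_volume_ml("L2") == pytest.approx(1.5, rel=0.10)

    def test_lesions_disjoint_and_inside_wall(self, desk_phantom):
        m1, m2 = desk_phantom.masks["L1"], desk_phantom.masks["L2"]
        assert not np.any(m1 & m2)
        lab = desk_phantom.label_map.data
        assert np.all(lab[m1] == ph.L1)
        assert np.all(lab[m2] == ph.L2)
        # LV mask excludes lesion voxels
        assert not np.any(desk_phantom.masks["LV"] & (m1 | m2))

    def test_l1_transmurality(self, heart_fov_phantom):
        """L1 crosses ~60 % of the wall at its centre (one-voxel tolerance)."""
        p = heart_fov_phantom.params
        m = heart_fov_phantom.masks["L1"]
        img = heart_fov_phantom.activity_true
        x, y, z = img.coord_grids()
        cx, cy, cz = p.lv_centre
        # radial span of the lesion at its central z-slab, against the wall span
        ix, iy, iz = np.nonzero(m)
        zc = np.bincount(iz).argmax()  # central slab by voxel count
        sl = m[:, :, zc]
        lab = heart_fov_phantom.label_map.data[:, :, zc]
        wall_sl = (lab == ph.LV_MYO) | (lab == ph.L1) | (lab == ph.L2)
        rr = np.sqrt((x[:, :, zc] - cx) ** 2 + (y[:, :, zc] - cy) ** 2)
        th = np.degrees(np.arctan2(x[:, :, zc] - cx, y[:, :, zc] - cy)) % 360
        central = np.abs(th - 120.0) < 3.0
        les_r = rr[sl & central]
        wall_r = rr[wall_sl & central]
        frac = (les_r.max() - les_r.min()) / (wall_r.max() - wall_r.min())
        vox = p.voxel_mm / p.lv_wall_mm
        assert frac == pytest.approx(0.60, abs=2 * vox)

    def test_wall_volume_matches_analytic_shell(self, heart_fov_phantom):
        p = heart_fov_phantom.params
        a0, c0 = p.lv_endo_semi
        a1, c1 = p.lv_epi_semi
        analytic_ml = (2.0 * np.pi / 3.0) * (a1 * a1 * c1 - a0 * a0 * c0) / 1000.0
        lab = heart_fov_phantom.label_map.data
        wall = (lab == ph.LV_MYO) | (lab == ph.L1) | (lab == ph.L2)
        measured = wall.sum() * heart_fov_phantom.activity_true.voxel_volume_ml
        assert measured == pytest.approx(analytic_ml, rel=0.05)

    def test_mu_map_consistent_with_labels(self, desk_phantom):
        mu = desk_phantom.mu_map.data
        lab = desk_phantom.label_map.data
        assert np.all(mu[lab == ph.LUNG] == pytest.approx(0.027))
        assert np.all(mu[lab == ph.BONE] == pytest.approx(0.120))
        assert np.all(mu[lab == ph.AIR] == 0.0)

    def test_deterministic_given_seed(self):
        a = build_phantom(PhantomParams.desk(seed=5))
        b = build_phantom(PhantomParams.desk(seed=5))
        assert np.array_equal(a.mr.data, b.mr.data)
        assert np.array_equal(a.activity_true.data, b.activity_true.data)

    def test_impossible_lesion_raises(self):
        params = PhantomParams.desk()
        with pytest.raises(GeometryError):
            LesionSpec("bad", 3.0, 1.5, 120.0, 30.0, (0.3, 0.6), 8.0)
        params.lesions = (LesionSpec("huge", 500.0, 1.0, 180.0, 45.0,
                                     (0.2, 0.35), 0.0, grow="long"),)
        with pytest.raises(GeometryError):
            build_phantom(params)


class TestDerivedAnatomies:
    def test_hrct_hounsfield_definition(self, desk_phantom):
        hu = desk_phantom.hrct.data
        lab = desk_phantom.label_map.data
        assert np.all(hu[lab == ph.LV_MYO] == pytest.approx(0.0))    # mu = mu_water
        assert np.all(hu[lab == ph.AIR] == pytest.approx(-1000.0))
        assert np.all(hu[lab == ph.BLOOD] == pytest.approx(300.0))   # contrast

    def test_hrct_has_no_lesion_contrast(self, desk_phantom):
        hu = desk_phantom.hrct.data
        lab = desk_phantom.label_map.data
        lv_val = hu[lab == ph.LV_MYO][0]
        assert np.all(hu[desk_phantom.masks["L1"]] == lv_val)
        assert np.all(hu[desk_phantom.masks["L2"]] == lv_val)

    def test_hrct_alignment_check(self, desk_phantom):
        other = Image(np.zeros((4, 4, 4)), 2.0)
        with pytest.raises(ConfigurationError):
            derive_hrct(desk_phantom.mu_map, other)

    def test_mr_noiseless_equals_class_map(self, desk_phantom):
        mr0 = derive_mr(desk_phantom.label_map, rician_sigma=0.0)
        lab = desk_phantom.label_map.data
        assert np.all(mr0.data[lab == ph.FAT] == 100.0)
        assert np.all(mr0.data[lab == ph.BONE] == 0.0)
        assert np.all(mr0.data[lab == ph.LV_MYO] == 10.0)
        assert np.all(mr0.data[desk_phantom.masks["L1"]] == 55.0)

    def test_mr_sigma_to_zero_converges(self, desk_phantom):
        clean = derive_mr(desk_phantom.label_map, rician_sigma=0.0)
        sup = [np.abs(derive_mr(desk_phantom.label_map, rician_sigma=s,
                                seed=3).data - clean.data).max()
               for s in (2.0, 0.2, 0.02)]
        assert sup[0] > sup[1] > sup[2]
        assert sup[2] < 0.5

    def test_mr_missing_class_raises(self, desk_phantom):
        with pytest.raises(ConfigurationError):
            derive_mr(desk_phantom.label_map, intensities={0: 0.0})

    def test_mr_deterministic(self, desk_phantom):
        a = derive_mr(desk_phantom.label_map, rician_sigma=5.0, seed=11)
        b = derive_mr(desk_phantom.label_map, rician_sigma=5.0, seed=11)
        assert np.array_equal(a.data, b.data)


class TestAnisotropy:
    def test_identity_at_native_thickness(self, rng):
        img = Image(rng.random((8, 8, 8)), 2.0)
        out = make_anisotropic(img, 2.0)
        assert np.array_equal(out.data, img.data)

    def test_constant_unchanged(self):
        img = Image(np.full((8, 8, 8), 3.3), 2.0)
        assert np.allclose(make_anisotropic(img, 8.0).data, 3.3)

    def test_block_average_oracle_on_step(self):
        img = Image(np.zeros((4, 4, 8)), 2.0)
        img.data[:, :, 5:] = 10.0  # axial step inside the second 8 mm slab
        out = make_anisotropic(img, 8.0)
        assert np.allclose(out.data[:, :, :4], 0.0)
        assert np.allclose(out.data[:, :, 4:], 10.0 * 3 / 4)  # slab mean

    def test_non_multiple_thickness_raises(self):
        img = Image(np.zeros((4, 4, 8)), 2.0)
        with pytest.raises(ConfigurationError):
            make_anisotropic(img, 5.0)


class TestShifts:
    def test_zero_shift_identity(self, rng):
        img = Image(rng.random((6, 6, 6)), 2.0)
        assert np.allclose(shift_image(img, (0, 0, 0)).data, img.data)

    def test_one_voxel_pitch_is_integer_roll(self, rng):
        img = Image(rng.random((8, 8, 8)), 2.0)
        out = shift_image(img, (2.0, 0.0, 0.0))
        assert np.allclose(out.data[1:], img.data[:-1], atol=1e-12)
        assert np.allclose(out.data[0], 0.0)

    def test_round_trip_interior(self):
        # linear interpolation is exact only up to curvature: use a smooth field
        img = Image(np.zeros((16, 16, 16)), 2.0)
        x, y, z = img.coord_grids()
        img.data[:] = np.sin(x / 8.0) * np.cos(y / 10.0) + 0.1 * z / 16.0
        back = shift_image(shift_image(img, (1.3, -0.7, 2.1)), (-1.3, 0.7, -2.1))
        interior = (slice(3, -3),) * 3
        assert np.allclose(back.data[interior], img.data[interior], atol=0.05)

    def test_random_shift_vectors(self):
        vecs = random_shift_vectors([1, 2, 4, 6], 10, seed=4)
        assert len(vecs) == 40
        mags = np.repeat([1, 2, 4, 6], 10)
        assert np.allclose([np.linalg.norm(v) for v in vecs], mags, atol=1e-9)
        again = random_shift_vectors([1, 2, 4, 6], 10, seed=4)
        assert all(np.array_equal(a, b) for a, b in zip(vecs, again))


class TestMismatchAndBreathing:
    def test_identity_mismatch(self, desk_phantom):
        same = mismatch_phantom(desk_phantom.params, 1.0, 0.0)
        assert np.array_equal(same.label_map.data, desk_phantom.label_map.data)

    @pytest.mark.parametrize("scale", [0.9, 1.05])
    def test_heart_volume_scaling(self, desk_phantom, scale):
        import cardiacpvc.phantom as P
        mism = mismatch_phantom(desk_phantom.params, heart_scale=scale)
        heart_labels = (P.LV_MYO, P.RV_MYO, P.BLOOD, P.L1, P.L2)
        def vol(s):
            lab = s.label_map.data
            return sum((lab == l).sum() for l in heart_labels)
        assert vol(mism) / vol(desk_phantom) == pytest.approx(scale, rel=0.04)

    def test_respiratory_states(self, desk_phantom):
        states = respiratory_states(desk_phantom.params, 5)
        assert len(states) == 5
        assert np.array_equal(states[0].activity_true.data,
                              desk_phantom.activity_true.data)
        import cardiacpvc.phantom as P
        cents = []
        for s in states:
            m = s.label_map.data == P.LV_MYO
            iz = np.nonzero(m)[2]
            cents.append(s.activity_true.axis_coords(2)[iz].mean())
        # cranio-caudal displacement spans the diaphragm amplitude, monotone
        assert cents[0] - cents[-1] == pytest.approx(20.0, abs=1.0)
        assert np.all(np.diff(cents) < 0)

    def test_single_state_is_reference(self, desk_phantom):
        states = respiratory_states(desk_phantom.params, 1)
        assert len(states) == 1
        assert np.array_equal(states[0].mu_map.data, desk_phantom.mu_map.data)


class TestRegionMasks:
    def test_1d_threshold_rule(self):
        profile = np.array([10.0, 9.0, 7.0, 6.9, 0.0])
        mask = threshold_region_mask(profile, np.ones(5, bool), 10.0, 0.7)
        assert mask.sum() == 3  # the >= 7.0 rule keeps exactly three samples

    def test_full_threshold_on_native_grid(self, desk_phantom):
        rm = region_masks(desk_phantom, desk_phantom.activity_true.voxel_mm[0],
                          desk_phantom.activity_true.shape, 1.0)
        assert np.array_equal(rm["LV"], desk_phantom.masks["LV"])

    def test_downsampled_containment(self, desk_phantom):
        from cardiacpvc.image import block_average
        rm = region_masks(desk_phantom, 3.0, (64, 64, 64), 0.7)
        ind = block_average(
            Image(desk_phantom.masks["LV"].astype(float), 2.0), 3.0,
            (64, 64, 64)).data
        assert rm["LV"].any()
        assert np.all(ind[rm["LV"]] > 0)  # strictly inside the label support

    def test_bad_threshold_raises(self, desk_phantom):
        with pytest.raises(ConfigurationError):
            region_masks(desk_phantom, 3.0, (64, 64, 64), 0.0)
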