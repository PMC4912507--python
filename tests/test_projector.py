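"""Acquisition model: ray tracing, attenuation, PSF, noise, gating."""

import math

import numpy as np
import pytest

from cardiacpvc.image import Image
from cardiacpvc.projector import (GateBudget, PsfModel, Sinogram,
                                  SinogramGeometry, attenuation_factors,
                                  back_project, forward_project,
                                  fwhm_to_sigma, gate_budget, gaussian_blur,
                                  get_projector, poisson_realizations,
                                  simulate_acquisition)


class TestFwhmSigma:
    @pytest.mark.parametrize("fwhm,sigma", [
        (0.0, 0.0),
        (4.3, 1.8260),   # 4.3 / 2.3548
        (5.0, 2.1233),
    ])
    def test_closed_form(self, fwhm, sigma):
        assert fwhm_to_sigma(fwhm) == pytest.approx(sigma, abs=1e-4)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            fwhm_to_sigma(-1.0)


class TestGaussianBlur:
    def test_constant_unchanged(self):
        img = Image(np.full((16, 16, 16), 4.2), 2.0)
        out = gaussian_blur(img, PsfModel(4.3, 4.5))
        inner = (slice(4, -4),) * 3
        assert np.allclose(out.data[inner], 4.2, atol=1e-10)

    def test_point_source_fwhm(self):
        n, v = 41, 1.0
        img = Image(np.zeros((n, n, n)), v)
        img.data[20, 20, 20] = 1.0
        out = gaussian_blur(img, PsfModel(5.0, 5.0)).data
        prof = out[:, 20, 20]
        half = prof.max() / 2.0
        above = np.nonzero(prof >= half)[0]
        measured = (above.max() - above.min() + 1) * v
        assert measured == pytest.approx(5.0, abs=v / 2 + 1e-9)

    def test_sum_conserved_interior_source(self):
        img = Image(np.zeros((32, 32, 32)), 2.0)
        img.data[14:18, 14:18, 14:18] = 3.0
        out = gaussian_blur(img, PsfModel(4.3, 4.5))
        assert out.data.sum() == pytest.approx(img.data.sum(), rel=1e-6)

    def test_gaussian_semigroup(self, rng):
        """Two successive blurs of FWHM a, b equal one blur of sqrt(a^2+b^2).

        Holds for kernels well resolved by the grid (sigma >= ~1.5 voxels);
        compact interior support keeps the zero padding out of the picture.
        """
        img = Image(np.zeros((48, 48, 48)), 2.0)
        img.data[18:30, 18:30, 18:30] = rng.random((12, 12, 12))
        twice = gaussian_blur(gaussian_blur(img, PsfModel(8, 8)), PsfModel(6, 6))
        once = gaussian_blur(img, PsfModel(10, 10))  # sqrt(64 + 36) = 10
        assert np.allclose(twice.data, once.data, atol=1e-6)


class TestProjectorPair:
    GEOM = SinogramGeometry(12, 16, 2.0)

    def test_zero_image(self):
        img = Image(np.zeros((8, 8, 2)), 2.0)
        assert np.all(forward_project(img, self.GEOM).values == 0.0)

    def test_matches_dense_system_matrix(self, rng):
        """Forward projection equals the dense matrix built by projecting
        unit voxels, column by column."""
        img = Image(rng.random((8, 8, 1)), 2.0)
        sino = forward_project(img, self.GEOM).values.ravel()
        dense = np.zeros((self.GEOM.n_angles * self.GEOM.n_radial, 64))
        for j in range(64):
            e = Image(np.zeros((8, 8, 1)), 2.0)
            e.data.ravel()[j] = 1.0
            dense[:, j] = forward_project(e, self.GEOM).values.ravel()
        assert np.abs(sino - dense @ img.data.ravel()).max() < 1e-8

    def test_adjoint_identity(self, rng):
        x = Image(rng.random((8, 8, 3)), 2.0)
        y = Sinogram(self.GEOM, rng.random((12, 16, 3)))
        fx = forward_project(x, self.GEOM)
        bty = back_project(y, (8, 8, 3), (2.0, 2.0, 2.0))
        lhs = (fx.values * y.values).sum()
        rhs = (x.data * bty.data).sum()
        assert abs(lhs - rhs) < 1e-8 * max(abs(lhs), 1.0)

    def test_linearity(self, rng):
        a = Image(rng.random((8, 8, 1)), 2.0)
        b = Image(rng.random((8, 8, 1)), 2.0)
        lhs = forward_project(Image(2.0 * a.data + 3.0 * b.data, 2.0), self.GEOM).values
        rhs = 2.0 * forward_project(a, self.GEOM).values \
            + 3.0 * forward_project(b, self.GEOM).values
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_central_ray_chord_of_disc(self):
        n, v, r, a = 64, 1.0, 20.0, 3.0
        img = Image(np.zeros((n, n, 1)), v)
        x, y, _ = img.coord_grids()
        img.data[(x ** 2 + y ** 2) <= r ** 2] = a
        geom = SinogramGeometry(4, 80, 1.0)
        sino = forward_project(img, geom)
        ib = int(np.argmin(np.abs(geom.radial_coords)))
        assert sino.values[0, ib, 0] == pytest.approx(2 * a * r, rel=0.01)

    def test_uniform_sinogram_backprojects_positive(self):
        geom = SinogramGeometry(16, 40, 2.0)
        sino = Sinogram(geom, np.ones((16, 40, 1)))
        img = back_project(sino, (16, 16, 1), (2.0, 2.0, 2.0))
        assert np.all(img.data > 0)

    def test_support_outside_fov_raises(self):
        img = Image(np.ones((100, 100, 1)), 2.0)  # 283 mm diagonal
        with pytest.raises(ValueError, match="field of view"):
            forward_project(img, SinogramGeometry(4, 40, 2.0))


class TestAttenuation:
    def test_zero_mu_gives_unity(self):
        img = Image(np.zeros((16, 16, 1)), 2.0)
        af = attenuation_factors(img, SinogramGeometry(8, 24, 2.0))
        assert np.allclose(af.values, 1.0)

    def test_uniform_disc_closed_form(self):
        # 0.096 cm^-1 over a 200 mm path: exp(-1.92)
        img = Image(np.zeros((120, 120, 1)), 2.0)
        x, y, _ = img.coord_grids()
        img.data[(x ** 2 + y ** 2) <= 100.0 ** 2] = 0.096
        geom = SinogramGeometry(1, 120, 2.0)
        af = attenuation_factors(img, geom)
        ib = int(np.argmin(np.abs(geom.radial_coords)))
        assert af.values[0, ib, 0] == pytest.approx(math.exp(-1.92), rel=5e-3)

    def test_monotone_in_mu_scaling(self, desk_phantom):
        from cardiacpvc.image import block_average
        mu = block_average(desk_phantom.mu_map, 4.0, (48, 48, 4))
        geom = SinogramGeometry.covering(mu, 8, 4.0)
        f1 = attenuation_factors(mu, geom).values
        f2 = attenuation_factors(Image(2.0 * mu.data, mu.voxel_mm), geom).values
        assert np.all(f2 <= f1 + 1e-12)

    def test_negative_mu_raises(self):
        img = Image(np.full((8, 8, 1), -0.01), 2.0)
        with pytest.raises(ValueError):
            attenuation_factors(img, SinogramGeometry(4, 16, 2.0))


class TestSimulateAcquisition:
    def _toy(self):
        act = Image(np.zeros((32, 32, 2)), 4.0)
        act.data[10:20, 10:20, :] = 5.0
        mu = Image(np.zeros((32, 32, 2)), 4.0)
        mu.data[8:24, 8:24, :] = 0.05
        geom = SinogramGeometry(8, 52, 4.0)
        return act, mu, geom

    def test_total_counts_calibration(self):
        act, mu, geom = self._toy()
        sino = simulate_acquisition(act, mu, geom, PsfModel(), 1e6)
        assert sino.values.sum() == pytest.approx(1e6, rel=1e-6)

    def test_invariant_to_activity_scale(self):
        act, mu, geom = self._toy()
        a = simulate_acquisition(act, mu, geom, PsfModel(), 1e6)
        b = simulate_acquisition(Image(7.0 * act.data, act.voxel_mm), mu,
                                 geom, PsfModel(), 1e6)
        assert np.allclose(a.values, b.values, rtol=1e-12)
        assert b.calibration == pytest.approx(a.calibration / 7.0)

    def test_no_psf_no_mu_equals_scaled_projection(self):
        act, _, geom = self._toy()
        mu0 = Image(np.zeros(act.shape), act.voxel_mm)
        sino = simulate_acquisition(act, mu0, geom, None, 1e5)
        proj = forward_project(act, geom).values
        assert np.allclose(sino.values, proj * 1e5 / proj.sum(), rtol=1e-12)

    def test_zero_signal_raises(self):
        act, mu, geom = self._toy()
        with pytest.raises(ValueError):
            simulate_acquisition(Image(np.zeros(act.shape), act.voxel_mm),
                                 mu, geom, None, 1e5)


class TestPoisson:
    def test_zero_expectation(self):
        geom = SinogramGeometry(4, 8, 2.0)
        s = Sinogram(geom, np.zeros((4, 8, 1)))
        assert np.all(poisson_realizations(s, 2, 0)[0].values == 0)

    def test_seed_reproducibility(self):
        geom = SinogramGeometry(4, 8, 2.0)
        s = Sinogram(geom, np.full((4, 8, 1), 9.0))
        a = poisson_realizations(s, 3, 42)
        b = poisson_realizations(s, 3, 42)
        assert all(np.array_equal(x.values, y.values) for x, y in zip(a, b))
        assert not np.array_equal(a[0].values, a[1].values)

    def test_sample_mean_matches_expectation(self):
        """Bin with expectation 7: mean over 1e4 draws within 3 sigma."""
        geom = SinogramGeometry(1, 1, 2.0)
        s = Sinogram(geom, np.full((1, 1, 1), 7.0))
        draws = [r.values[0, 0, 0] for r in poisson_realizations(s, 10000, 3)]
        assert np.mean(draws) == pytest.approx(7.0, abs=3 * math.sqrt(7 / 1e4))


class TestGateBudget:
    def test_dual_gate_36s(self):
        b = gate_budget(30, 5, 10, "DUAL")
        assert b == GateBudget(36.0, 1.0, False)

    def test_ecg_gate_180s(self):
        b = gate_budget(30, 5, 10, "ECG")
        assert b.seconds == 180.0
        assert b.count_scale == 5.0
        assert b.average_respiratory_states

    def test_ecg_plus_r(self):
        b = gate_budget(30, 5, 10, "ECG+R")
        assert b.seconds == 180.0 and not b.average_respiratory_states

    def test_ungated(self):
        assert gate_budget(30, 1, 1, "DUAL").seconds == 1800.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            gate_budget(30, 0, 10, "DUAL")
        with pytest.raises(ValueError):
            gate_budget(30, 5, 10, "WHAT")
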